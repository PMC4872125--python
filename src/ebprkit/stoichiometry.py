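"""Anaerobic/aerobic transformation ratios from EBPR batch-cycle time series.

A sequencing-batch cycle alternates an anaerobic phase, in which
polyphosphate-accumulating organisms (PAOs) take up acetate, release
orthophosphate and store the carbon as poly-beta-hydroxyalkanoates (PHA,
the sum of its PHB and PHV fractions) while degrading glycogen, and an
aerobic phase, in which the stored PHA is oxidised to take phosphate back
up and replenish glycogen.  The biochemical signature of a cycle is
summarised by seven endpoint ratios:

anaerobic (per C-mol acetate consumed)
    P/HAc, Gly/HAc, PHB/HAc, PHV/HAc, PHA/HAc
aerobic (per C-mol PHA consumed)
    P/PHA, Gly/PHA

Liquid-phase analytes (acetate, orthophosphate) are normalised by the
volatile-suspended-solids (VSS) concentration so every delta is expressed
per gram of biomass; intracellular analytes (PHB, PHV, glycogen) are
already biomass-normalised.  Deltas are endpoint differences (|end - start|
of the phase), the standard convention for batch-test stoichiometry; a
regression-based alternative is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError

ANAEROBIC = "anaerobic"
AEROBIC = "aerobic"
PHASES = (ANAEROBIC, AEROBIC)

#: analytes measured in the liquid phase (per litre); divided by VSS
LIQUID_ANALYTES = ("acetate", "phosphate")
#: analytes measured in the biomass (already per g VSS)
BIOMASS_ANALYTES = ("phb", "phv", "glycogen")
ANALYTES = LIQUID_ANALYTES + BIOMASS_ANALYTES

RATIO_FIELDS = (
    "p_per_hac",
    "gly_per_hac",
    "phb_per_hac",
    "phv_per_hac",
    "pha_per_hac",
    "p_per_pha",
    "gly_per_pha",
)


@dataclass
class BatchTimeSeries:
    """Timestamped analyte concentrations over one anaerobic/aerobic cycle.

    Parameters
    ----------
    data:
        Frame with columns ``time_min``, ``phase`` plus at least one analyte
        column among :data:`ANALYTES` and ``vss`` (g/L).  Acetate is in
        C-mmol/L, phosphate in P-mmol/L, PHB/PHV/glycogen in C-mmol per
        g VSS.
    replicate_id:
        Label of the (duplicate) lab-scale reactor the cycle came from.
    date:
        Sampling date of the cycle (ISO string), if known.
    """

    data: pd.DataFrame
    replicate_id: str = "r1"
    date: Optional[str] = None

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time_min", "phase"):
            if col not in df.columns:
                raise ValidationError(f"required column {col!r} missing")
        bad = set(df["phase"].unique()) - set(PHASES)
        if bad:
            raise ValidationError(
                f"unknown phase label(s) {sorted(bad)!r}; expected one of {PHASES}"
            )
        t = df["time_min"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise ValidationError("time_min must be non-decreasing")
        present = [a for a in ANALYTES if a in df.columns]
        if not present:
            raise ValidationError("no analyte column present")
        for a in present + (["vss"] if "vss" in df.columns else []):
            vals = df[a].to_numpy(float)
            if np.any(vals[~np.isnan(vals)] < 0):
                raise ValidationError(f"negative concentration in column {a!r}")
        # phase labels must form contiguous blocks in time order
        ph = df["phase"].to_numpy()
        changes = sum(ph[i] != ph[i - 1] for i in range(1, len(ph)))
        if changes >= len(set(ph)):
            raise ValidationError("phase labels do not form contiguous blocks")
        self.data = df.reset_index(drop=True)

    @property
    def analytes(self) -> List[str]:
        return [a for a in ANALYTES if a in self.data.columns]

    def phase_slice(self, phase: str) -> pd.DataFrame:
        if phase not in PHASES:
            raise ValidationError(f"unknown phase {phase!r}")
        return self.data[self.data["phase"] == phase]


class AnalyteDelta(NamedTuple):
    """Magnitude (always >= 0) and direction (+1 produced, -1 consumed, 0 flat)."""

    magnitude: float
    direction: int


@dataclass
class StoichiometricRatios:
    """The seven per-cycle transformation ratios (NaN where not measured)."""

    p_per_hac: float = math.nan
    gly_per_hac: float = math.nan
    phb_per_hac: float = math.nan
    phv_per_hac: float = math.nan
    pha_per_hac: float = math.nan
    p_per_pha: float = math.nan
    gly_per_pha: float = math.nan
    epoch: Optional[str] = None
    date: Optional[str] = None
    replicate_id: Optional[str] = None

    def as_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in RATIO_FIELDS})


@dataclass
class EpochSummary:
    """Per-ratio mean and sample (n-1) standard deviation over the cycles of an epoch."""

    epoch: str
    mean: pd.Series
    sd: pd.Series
    n_cycles: int

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        """Report-time rounding; computations always use full precision.

        Ties (exact halves, which arise when averaging 2-decimal inputs)
        are rounded toward zero, the convention of the survey report this
        summary format follows.
        """
        return pd.DataFrame(
            {
                "mean": self.mean.map(lambda v: round_half_down(v, ndigits)),
                "sd": self.sd.map(lambda v: round_half_down(v, ndigits)),
            }
        )


def round_half_down(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties toward zero, robust to float representation.

    The float is first snapped to a 9-decimal grid so that quantities that
    are exact decimal halves in real arithmetic (e.g. the mean of 2-decimal
    measurements) are recognised as ties despite binary round-off.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    from decimal import ROUND_HALF_DOWN, ROUND_HALF_EVEN, Decimal

    snapped = Decimal(repr(float(value))).quantize(Decimal("1e-9"), ROUND_HALF_EVEN)
    return float(snapped.quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_DOWN))


def phase_deltas(
    ts: BatchTimeSeries, phase: str, method: str = "endpoint"
) -> Dict[str, AnalyteDelta]:
    """Per-analyte change over a phase, in C-/P-mmol per g VSS.

    ``method="endpoint"`` (default) differences the last and first samples of
    the phase; ``method="regression"`` uses an OLS slope times the phase
    duration, for sensitivity analysis on noisy series.
    """
    sub = ts.phase_slice(phase)
    if len(sub) < 2:
        raise ValidationError(f"phase {phase!r} needs >=2 points, got {len(sub)}")
    if "vss" in sub.columns:
        vss = float(sub["vss"].mean())
    else:
        vss = 1.0
    if not vss > 0:
        raise ValidationError("VSS must be > 0")

    out: Dict[str, AnalyteDelta] = {}
    t = sub["time_min"].to_numpy(float)
    for analyte in ts.analytes:
        y = sub[analyte].to_numpy(float)
        if np.all(np.isnan(y)):
            continue
        if method == "endpoint":
            change = y[-1] - y[0]
        elif method == "regression":
            slope = np.polyfit(t, y, 1)[0]
            change = slope * (t[-1] - t[0])
        else:
            raise ValidationError(f"unknown delta method {method!r}")
        if analyte in LIQUID_ANALYTES:
            change /= vss
        direction = 0 if change == 0 else (1 if change > 0 else -1)
        out[analyte] = AnalyteDelta(abs(float(change)), direction)
    return out


def anaerobic_ratios(ts: BatchTimeSeries, method: str = "endpoint") -> StoichiometricRatios:
    """P/HAc, Gly/HAc, PHB/HAc, PHV/HAc and PHA/HAc from the anaerobic phase.

    PHA/HAc is PHB/HAc + PHV/HAc by construction.  Missing analytes give
    NaN ratios, never zeros.
    """
    d = phase_deltas(ts, ANAEROBIC, method=method)
    if "acetate" not in d:
        raise UndefinedRatioError("acetate not measured; anaerobic ratios undefined")
    dhac = d["acetate"].magnitude
    if dhac == 0:
        raise UndefinedRatioError("no acetate consumed (delta HAc = 0)")

    def ratio(name: str) -> float:
        return d[name].magnitude / dhac if name in d else math.nan

    phb = ratio("phb")
    phv = ratio("phv")
    pha = phb + phv if not (math.isnan(phb) or math.isnan(phv)) else math.nan
    return StoichiometricRatios(
        p_per_hac=ratio("phosphate"),
        gly_per_hac=ratio("glycogen"),
        phb_per_hac=phb,
        phv_per_hac=phv,
        pha_per_hac=pha,
        date=ts.date,
        replicate_id=ts.replicate_id,
    )


def aerobic_ratios(ts: BatchTimeSeries, method: str = "endpoint") -> StoichiometricRatios:
    """P/PHA and Gly/PHA from the aerobic phase.

    P/PHA is the aerobic phosphate uptake per C-mol of PHA consumed;
    Gly/PHA the glycogen replenished per C-mol PHA.  A missing glycogen
    column yields a NaN Gly/PHA while the other ratio is still computed.
    """
    d = phase_deltas(ts, AEROBIC, method=method)
    dpha = 0.0
    seen = False
    for name in ("phb", "phv"):
        if name in d:
            dpha += d[name].magnitude
            seen = True
    if not seen or dpha == 0:
        raise UndefinedRatioError("no PHA consumed (delta PHA = 0)")
    p = d["phosphate"].magnitude / dpha if "phosphate" in d else math.nan
    gly = d["glycogen"].magnitude / dpha if "glycogen" in d else math.nan
    return StoichiometricRatios(
        p_per_pha=p, gly_per_pha=gly, date=ts.date, replicate_id=ts.replicate_id
    )


def cycle_ratios(ts: BatchTimeSeries, method: str = "endpoint") -> StoichiometricRatios:
    """All seven ratios of one batch cycle (anaerobic + aerobic phases)."""
    ana = anaerobic_ratios(ts, method=method)
    aer = aerobic_ratios(ts, method=method)
    ana.p_per_pha = aer.p_per_pha
    ana.gly_per_pha = aer.gly_per_pha
    return ana


def average_replicates(per_cycle: Sequence[StoichiometricRatios]) -> StoichiometricRatios:
    """Average duplicate-reactor ratios of one sampling date at the ratio level."""
    if not per_cycle:
        raise ValidationError("no ratios to average")
    frame = pd.DataFrame([r.as_series() for r in per_cycle])
    mean = frame.mean(skipna=True)
    first = per_cycle[0]
    return StoichiometricRatios(
        **{f: float(mean[f]) for f in RATIO_FIELDS},
        epoch=first.epoch,
        date=first.date,
        replicate_id="mean",
    )


def epoch_summary(ratios: Iterable[StoichiometricRatios], epoch: str) -> EpochSummary:
    """Arithmetic mean and sample s.d. of each ratio over the cycles of an epoch.

    Missing (NaN) values are ignored ratio-by-ratio.  The s.d. is the n-1
    sample standard deviation and is NaN for a single cycle.
    """
    pool = list(ratios)
    rows = [r for r in pool if r.epoch == epoch]
    if not rows and all(r.epoch is None for r in pool):
        rows = pool  # unlabelled input: caller pre-selected the epoch
    if not rows:
        raise ValidationError(f"no cycles in epoch {epoch!r}")
    frame = pd.DataFrame([r.as_series() for r in rows])
    return EpochSummary(
        epoch=epoch,
        mean=frame.mean(skipna=True),
        sd=frame.std(ddof=1, skipna=True),
        n_cycles=len(rows),
    )


# ---------------------------------------------------------------------------
# Bundled reference dataset: per-date transformation ratios measured over a
# ten-event survey of a full-scale tropical EBPR plant, four cycles under
# high aeration followed by six under reduced aeration.  Gly/PHA was not
# measured on the first low-aeration date.
_REFERENCE_ROWS = [
    # date, epoch, P/HAc, Gly/HAc, PHB/HAc, PHV/HAc, PHA/HAc, P/PHA, Gly/PHA
    ("2013-05-29", "high", 0.92, 0.74, 0.51, 0.06, 0.57, 0.67, 0.67),
    ("2013-06-05", "high", 0.80, 0.63, 0.69, 0.07, 0.76, 0.90, 0.52),
    ("2013-06-12", "high", 1.01, 0.58, 0.84, 0.13, 0.97, 0.73, 0.60),
    ("2013-06-19", "high", 0.83, 0.44, 1.30, 0.20, 1.50, 0.73, 0.64),
    ("2013-06-26", "low", 0.82, 0.34, 0.94, 0.17, 1.11, 0.82, math.nan),
    ("2013-07-03", "low", 0.99, 0.39, 0.96, 0.20, 1.16, 0.84, 0.53),
    ("2013-07-10", "low", 0.86, 0.34, 1.03, 0.18, 1.21, 0.72, 0.49),
    ("2013-07-16", "low", 0.93, 0.37, 1.01, 0.21, 1.22, 0.75, 0.51),
    ("2013-07-25", "low", 0.94, 0.44, 0.90, 0.19, 1.09, 1.04, 0.47),
    ("2013-08-14", "low", 0.81, 0.38, 0.81, 0.19, 1.00, 0.76, 0.65),
]


def reference_cycle_ratios() -> List[StoichiometricRatios]:
    """Published per-cycle ratios of the tropical full-scale EBPR survey."""
    out = []
    for date, epoch, *vals in _REFERENCE_ROWS:
        out.append(
            StoichiometricRatios(
                **dict(zip(RATIO_FIELDS, (float(v) for v in vals))),
                epoch=epoch,
                date=date,
            )
        )
    return out
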