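"""Synthetic batch cycles, OTU count tables and shotgun reads with planted truth.

Every generator is a pure function of its spec (which includes the RNG
seed): identical specs give identical outputs.  The generators plant known
structure — stoichiometric ratios, abundance step factors, probe target
sites — so each downstream analysis stage can be checked for parameter
recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import InfeasibleSpecError, ValidationError
from .stoichiometry import BatchTimeSeries, StoichiometricRatios

# ---------------------------------------------------------------------------
# batch cycles


@dataclass
class BatchSimSpec:
    """Anaerobic/aerobic batch cycle with chosen endpoint stoichiometry.

    Defaults mirror a typical lab-scale test on full-scale sludge: acetate
    dosed at ~15 mg C/L (1.25 C-mmol/L), biomass at 1.65 g VSS/L, 3 h
    phases sampled at four points each.  The anaerobic endpoints realise
    ``target_ratios`` exactly before noise; the aerobic phase consumes the
    accumulated PHA and reverses phosphate and glycogen according to the
    aerobic targets.
    """

    target_ratios: StoichiometricRatios
    initial_acetate: float = 1.25  # C-mmol/L
    vss: float = 1.65  # g/L
    n_timepoints: int = 4  # per phase
    noise_sd: float = 0.0  # relative (multiplicative) Gaussian noise
    rng_seed: int = 0
    initial_phosphate: float = 1.3  # P-mmol/L
    baseline_phb: float = 0.3  # C-mmol/gVSS
    baseline_phv: float = 0.1
    baseline_glycogen: float = 2.0
    phase_minutes: float = 180.0

    def __post_init__(self) -> None:
        t = self.target_ratios
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_timepoints < 2:
            raise ValidationError("need >= 2 timepoints per phase")
        if not math.isnan(t.pha_per_hac):
            if abs(t.pha_per_hac - (t.phb_per_hac + t.phv_per_hac)) > 0.01:
                raise ValidationError("target PHA/HAc must equal PHB/HAc + PHV/HAc")


def gen_batch_timeseries(spec: BatchSimSpec) -> BatchTimeSeries:
    """Piecewise-linear batch cycle realising the planted ratios at the endpoints.

    Within-phase profiles are linear in time; the transformation ratios are
    endpoint-determined, so the within-phase shape does not affect them.
    """
    t = spec.target_ratios
    rng = np.random.default_rng(spec.rng_seed)
    dhac = spec.initial_acetate / spec.vss  # C-mmol/gVSS consumed anaerobically

    def delta(ratio: float) -> float:
        return 0.0 if math.isnan(ratio) else ratio * dhac

    p_release = delta(t.p_per_hac) * spec.vss  # back to liquid P-mmol/L
    gly_drop = delta(t.gly_per_hac)
    phb_gain = delta(t.phb_per_hac)
    phv_gain = delta(t.phv_per_hac)
    if gly_drop > spec.baseline_glycogen:
        raise InfeasibleSpecError(
            "target Gly/HAc would drive glycogen negative; raise baseline_glycogen"
        )

    dpha = phb_gain + phv_gain  # aerobic phase consumes the anaerobic PHA gain
    p_uptake = (0.0 if math.isnan(t.p_per_pha) else t.p_per_pha * dpha) * spec.vss
    gly_regain = 0.0 if math.isnan(t.gly_per_pha) else t.gly_per_pha * dpha
    if p_uptake > spec.initial_phosphate + p_release:
        raise InfeasibleSpecError(
            "target P/PHA would drive phosphate negative; raise initial_phosphate"
        )

    n = spec.n_timepoints
    frac = np.linspace(0.0, 1.0, n)
    times_an = frac * spec.phase_minutes
    times_ae = spec.phase_minutes + frac * spec.phase_minutes

    def ramp(start: float, change: float) -> np.ndarray:
        return start + change * frac

    ana = pd.DataFrame(
        {
            "time_min": times_an,
            "phase": "anaerobic",
            "acetate": ramp(spec.initial_acetate, -spec.initial_acetate),
            "phosphate": ramp(spec.initial_phosphate, p_release),
            "phb": ramp(spec.baseline_phb, phb_gain),
            "phv": ramp(spec.baseline_phv, phv_gain),
            "glycogen": ramp(spec.baseline_glycogen, -gly_drop),
            "vss": spec.vss,
        }
    )
    aer = pd.DataFrame(
        {
            "time_min": times_ae,
            "phase": "aerobic",
            "acetate": 0.0,
            "phosphate": ramp(spec.initial_phosphate + p_release, -p_uptake),
            "phb": ramp(spec.baseline_phb + phb_gain, -phb_gain),
            "phv": ramp(spec.baseline_phv + phv_gain, -phv_gain),
            "glycogen": ramp(spec.baseline_glycogen - gly_drop, gly_regain),
            "vss": spec.vss,
        }
    )
    frame = pd.concat([ana, aer], ignore_index=True)
    if spec.noise_sd > 0:
        analytes = ["acetate", "phosphate", "phb", "phv", "glycogen"]
        noise = rng.normal(1.0, spec.noise_sd, size=(len(frame), len(analytes)))
        frame[analytes] = (frame[analytes] * noise).clip(lower=0.0)
    if math.isnan(t.gly_per_hac) and math.isnan(t.gly_per_pha):
        frame = frame.drop(columns="glycogen")
    return BatchTimeSeries(frame, date=t.date)


# ---------------------------------------------------------------------------
# OTU count tables


@dataclass
class OtuSimSpec:
    """OTU counts across dated samples with an optional planted step change.

    The log10 expected abundance of OTU i at sample t is
    ``baseline_i + log10(step_factor_i) * 1[t > n1] + eps_it`` where the
    baselines are Normal(mean_log_baseline, log_baseline_sd) across OTUs
    and eps is stationary AR(1) noise (coefficient ``ar1_rho``, marginal sd
    ``log_noise_sd``).  Counts are a multinomial draw of ``depth`` reads per
    sample from the renormalised abundances, so column sums equal the depth
    exactly.
    """

    n_otus: int = 100
    n_samples: int = 10
    split: Tuple[int, int] = (4, 6)
    step_factor: object = 1.0  # scalar or per-OTU sequence; 1 = null
    ar1_rho: float = 0.0
    depth: int = 20_000
    log_baseline_sd: float = 1.0
    log_noise_sd: float = 0.25
    mean_log_baseline: float = -2.5  # log10 relative abundance scale
    rng_seed: int = 0
    start_date: str = "2013-05-29"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValidationError("ar1_rho must be in [0, 1)")
        if self.split[0] + self.split[1] != self.n_samples:
            raise ValidationError("split must sum to n_samples")
        sf = np.broadcast_to(np.asarray(self.step_factor, float), (self.n_otus,))
        if np.any(sf <= 0):
            raise ValidationError("step_factor must be > 0")


def gen_otu_counts(spec: OtuSimSpec):
    """Multinomially sampled OTU table with the planted step structure."""
    from .changepoint import OtuTable  # local import avoids a cycle at import time

    rng = np.random.default_rng(spec.rng_seed)
    n, s = spec.n_otus, spec.n_samples
    n1 = spec.split[0]
    sf = np.broadcast_to(np.asarray(spec.step_factor, float), (n,)).copy()

    baselines = rng.normal(spec.mean_log_baseline, spec.log_baseline_sd, size=n)
    eps = np.empty((n, s))
    innov = rng.standard_normal((n, s))
    eps[:, 0] = innov[:, 0]
    rho = spec.ar1_rho
    for t in range(1, s):
        eps[:, t] = rho * eps[:, t - 1] + math.sqrt(1 - rho**2) * innov[:, t]
    eps *= spec.log_noise_sd

    log_expected = baselines[:, None] + eps
    log_expected[:, n1:] += np.log10(sf)[:, None]
    weights = 10.0 ** log_expected
    probs = weights / weights.sum(axis=0)

    counts = np.column_stack(
        [rng.multinomial(spec.depth, probs[:, j]) for j in range(s)]
    )
    dates = pd.date_range(spec.start_date, periods=s, freq="7D").strftime("%Y-%m-%d")
    ids = [f"otu{i:04d}" for i in range(n)]
    tax = pd.Series(["k__Bacteria"] * n, index=ids)
    return OtuTable(
        counts=pd.DataFrame(counts, index=ids, columns=dates), taxonomy=tax
    )


# ---------------------------------------------------------------------------
# shotgun reads with planted probe sites


@dataclass
class ReadSimSpec:
    """Shotgun reads from a planted taxon mixture carrying probe target sites.

    Each read is assigned to a taxon by its abundance; it then carries one
    concrete realisation of every probe site of that taxon (per-site
    carriage probability ``site_rate``) embedded at a random offset on a
    random strand, plus the universal site with probability
    ``universal_fraction``.
    """

    taxon_abundances: Mapping[str, float] = field(
        default_factory=lambda: {"PAO": 0.5, "other": 0.5}
    )
    probe_sites: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    #: taxon -> {probe_id: IUPAC site sequence}
    universal_site: str = ""
    read_length: int = 150
    n_reads: int = 1000
    universal_fraction: float = 1.0
    site_rate: float = 1.0
    substitution_rate: float = 0.0  # uniform read-error rate, off by default
    randomize_strand: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.taxon_abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"taxon abundances must sum to 1, got {total}")
        longest = max(
            [len(s) for sites in self.probe_sites.values() for s in sites.values()]
            + ([len(self.universal_site)] if self.universal_site else [0])
        )
        if longest > self.read_length:
            raise InfeasibleSpecError("probe site longer than read_length")
        if not 0 <= self.universal_fraction <= 1 or not 0 <= self.site_rate <= 1:
            raise ValidationError("fractions must be in [0, 1]")


_BASES = np.array(list("ACGT"))
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")


def _concrete(site: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_IUPAC_CHOICES[c])) for c in site.upper())


def gen_reads_with_probes(spec: ReadSimSpec) -> Tuple[List[Tuple[str, str]], Dict]:
    """Reads as (id, sequence) pairs plus a truth sidecar of planted counts.

    Sites are embedded without mutual overlap by building each read as
    randomly split background segments interleaved with the concrete site
    sequences, so every planted site is guaranteed to be present verbatim
    (before optional substitution errors).
    """
    rng = np.random.default_rng(spec.rng_seed)
    taxa = list(spec.taxon_abundances)
    probs = np.array([spec.taxon_abundances[t] for t in taxa])
    assignment = rng.choice(len(taxa), size=spec.n_reads, p=probs)

    truth: Dict[str, int] = {"universal": 0}
    reads: List[Tuple[str, str]] = []
    for i in range(spec.n_reads):
        taxon = taxa[assignment[i]]
        sites: List[str] = []
        carried: List[str] = []
        if spec.universal_site and rng.random() < spec.universal_fraction:
            sites.append(_concrete(spec.universal_site, rng))
            truth["universal"] += 1
        for probe_id, site in spec.probe_sites.get(taxon, {}).items():
            if rng.random() < spec.site_rate:
                sites.append(_concrete(site, rng))
                carried.append(probe_id)
        total_site_len = sum(len(s) for s in sites)
        if total_site_len > spec.read_length:
            raise InfeasibleSpecError(
                f"sites ({total_site_len} nt) do not fit in a {spec.read_length} nt read"
            )
        for probe_id in carried:
            truth[probe_id] = truth.get(probe_id, 0) + 1

        if spec.randomize_strand:
            sites = [
                s if rng.random() < 0.5 else s.translate(_COMP)[::-1] for s in sites
            ]
        rng.shuffle(sites)
        n_bg = spec.read_length - total_site_len
        cuts = np.sort(rng.integers(0, n_bg + 1, size=len(sites)))
        background = "".join(rng.choice(_BASES, size=n_bg))
        parts = []
        prev = 0
        for cut, site in zip(cuts, sites):
            parts.append(background[prev:cut])
            parts.append(site)
            prev = cut
        parts.append(background[prev:])
        seq = "".join(parts)

        if spec.substitution_rate > 0:
            arr = np.array(list(seq))
            hit = rng.random(len(arr)) < spec.substitution_rate
            arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
            seq = "".join(arr)
        reads.append((f"read{i:06d}|{taxon}", seq))

    truth["n_reads"] = spec.n_reads
    truth["taxon_counts"] = {t: int(np.sum(assignment == k)) for k, t in enumerate(taxa)}
    return reads, truth
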