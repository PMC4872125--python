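"""Step-change detection on OTU time series with Storey-Tibshirani FDR control.

The survey design is ten dated samples, the first four under one operating
regime (the "high" aeration epoch) and the last six under another ("low").
Counts are rarefied to an even depth, log10(x+1) transformed, and each
ubiquitous OTU (nonzero in every sample) is tested for a step-like change
in mean level between the two epochs.  The step statistic is the
two-segment one-way ANOVA F at the known split, with the p-value from the
F(1, n-2) upper tail; the split is fixed by the experimental design, not
searched.  Multiplicity is handled by q-values with a smoothed estimate of
the null proportion pi0.

The module also contains the simulation machinery used to characterise the
test: statistical power across effect sizes and the false-positive rate
under AR(1) autocorrelation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

HIGH, LOW = "high", "low"


@dataclass
class OtuTable:
    """Integer OTU-by-sample count matrix with taxonomy annotations.

    counts:
        DataFrame indexed by OTU id; columns are ISO sample dates in
        ascending order.
    taxonomy:
        Semicolon-delimited ranked lineage string per OTU
        (``k__...; p__...; ...; g__...; s__...``).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate OTU id(s): {dups}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        self.taxonomy = self.taxonomy.reindex(self.counts.index).fillna("")
        dates = pd.to_datetime(self.counts.columns)
        order = np.argsort(dates.values, kind="stable")
        self.counts = self.counts.iloc[:, order]

    @property
    def sample_dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(pd.to_datetime(self.counts.columns))

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def epochs(self, boundary_date: Union[str, pd.Timestamp]) -> pd.Series:
        """Epoch label per sample: HIGH up to and including the boundary date."""
        b = pd.Timestamp(boundary_date)
        return pd.Series(
            [HIGH if d <= b else LOW for d in self.sample_dates],
            index=self.counts.columns,
        )

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts / totals


@dataclass
class StepChangeResult:
    difference: float
    f_statistic: float
    p_value: float
    flagged: bool = False  # zero within-segment variance with nonzero difference


@dataclass
class FoldChange:
    factor: float  # always reported >= 1 (NaN when undefined)
    direction: str  # "increase" | "decrease" | "none" | "undefined"


@dataclass
class ErrorRateReport:
    """Rejection rate of the step test over an (effect, rho) grid."""

    design: Tuple[int, int]
    alpha: float
    reps: int
    rng_seed: int
    rates: pd.DataFrame  # columns: effect, rho, rejection_rate


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Randomly subsample every sample to an even depth, without replacement.

    A single multivariate-hypergeometric draw per sample, so each OTU's
    subsampled count never exceeds its original count and every column of
    the result sums exactly to ``depth``.
    """
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    colsums = table.counts.sum(axis=0)
    short = colsums[colsums < depth]
    if len(short):
        raise ValidationError(
            f"depth {depth} exceeds the total count of sample(s): "
            + ", ".join(f"{s} ({colsums[s]})" for s in short.index)
        )
    rng = np.random.default_rng(seed)
    sub = np.column_stack(
        [
            rng.multivariate_hypergeometric(table.counts[c].to_numpy(), depth)
            for c in table.counts.columns
        ]
    )
    return OtuTable(
        counts=pd.DataFrame(sub, index=table.counts.index, columns=table.counts.columns),
        taxonomy=table.taxonomy.copy(),
    )


def log_normalize(table: OtuTable) -> pd.DataFrame:
    """log10 of unity-offset pseudo-counts: x -> log10(x + 1), elementwise."""
    return np.log10(table.counts + 1)


def taxon_relative_abundance(
    table: OtuTable, taxon: str
) -> Tuple[pd.Series, float, pd.Index]:
    """Relative abundance of all OTUs annotated to a taxon.

    ``taxon`` is matched as an exact rank token of the lineage string
    (e.g. ``"g__Candidatus Accumulibacter"``); unclassified ranks (bare
    ``g__``) never match a named query.  Returns per-sample fractions, the
    pooled overall fraction, and the matching OTU ids; a zero-match taxon
    gives all-zero abundances.
    """
    query = taxon.strip()
    if not query:
        raise ValidationError("empty taxon query")

    def matches(lineage: str) -> bool:
        tokens = [t.strip() for t in str(lineage).split(";")]
        return query in tokens or query == str(lineage).strip()

    hit = table.taxonomy.map(matches)
    ids = table.counts.index[hit.to_numpy(bool)]
    matched = table.counts.loc[ids].sum(axis=0)
    totals = table.counts.sum(axis=0)
    per_sample = matched / totals
    overall = float(matched.sum() / totals.sum())
    return per_sample, overall, ids


def parse_rank(lineage: str, prefix: str = "g__") -> Optional[str]:
    """Extract a named rank (default genus) from a lineage string, or None."""
    for token in str(lineage).split(";"):
        token = token.strip()
        if token.startswith(prefix):
            name = token[len(prefix):].strip()
            return name or None
    return None


def step_change_test(
    series: Sequence[float], split: Tuple[int, int]
) -> StepChangeResult:
    """Two-segment step-change statistic at a known split.

    difference = mean(second segment) - mean(first segment); F is the
    between/within mean-square ratio with (1, n-2) degrees of freedom and
    the p-value its upper tail.  A zero within-segment variance with a
    nonzero difference yields an infinite F and a floored, flagged p.
    """
    n1, n2 = split
    if n1 < 2 or n2 < 2:
        raise ValidationError("both segments need >= 2 points")
    x = np.asarray(series, float)
    if x.size != n1 + n2:
        raise ValidationError(f"series length {x.size} != n1 + n2 = {n1 + n2}")
    a, b = x[:n1], x[n1:]
    diff = float(b.mean() - a.mean())
    gm = x.mean()
    ssb = n1 * (a.mean() - gm) ** 2 + n2 * (b.mean() - gm) ** 2
    ssw = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    dof = n1 + n2 - 2
    if ssb <= 0:
        return StepChangeResult(diff, 0.0, 1.0)
    if ssw == 0:
        return StepChangeResult(diff, math.inf, float(np.finfo(float).tiny), flagged=True)
    f = float(ssb / (ssw / dof))
    p = float(stats.f.sf(f, 1, dof))
    return StepChangeResult(diff, f, p)


def _step_test_batch(x: np.ndarray, n1: int) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised step test over the rows of ``x`` (reps, n1+n2)."""
    a, b = x[:, :n1], x[:, n1:]
    n2 = x.shape[1] - n1
    am, bm = a.mean(axis=1), b.mean(axis=1)
    gm = x.mean(axis=1)
    ssb = n1 * (am - gm) ** 2 + n2 * (bm - gm) ** 2
    ssw = ((a - am[:, None]) ** 2).sum(axis=1) + ((b - bm[:, None]) ** 2).sum(axis=1)
    dof = x.shape[1] - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / dof)
    f = np.where(ssb <= 0, 0.0, f)
    p = stats.f.sf(f, 1, dof)
    return f, p


def qvalues(
    p: Sequence[float], pi0: Optional[float] = None
) -> Tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values and the estimated null proportion pi0.

    pi0 is estimated by fitting a cubic smoother to
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over
    lambda in {0.05, 0.10, ..., 0.95} and evaluating it at lambda = 0.95;
    for fewer than 100 p-values the single-lambda estimate at 0.5 is used.
    q(p_i) = min over p_(j) >= p_i of pi0 * m * p_(j) / j, which is
    monotone in p and reduces to Benjamini-Hochberg when pi0 = 1.
    """
    p = np.asarray(p, float)
    m = p.size
    if m == 0:
        raise ValidationError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValidationError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def estimate_pi0(p: Sequence[float]) -> float:
    """Smoothed estimate of the proportion of true null hypotheses."""
    p = np.asarray(p, float)
    m = p.size
    if m < 100:
        lam = 0.5
        return float(min(1.0, max(np.mean(p > lam) / (1 - lam), 1.0 / m)))
    lams = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > lam) / (1 - lam) for lam in lams])
    coef = np.polyfit(lams, pi0_lam, 3)
    pi0 = float(np.polyval(coef, 0.95))
    return float(min(1.0, max(pi0, 1.0 / m)))


def epoch_fold_change(
    table: OtuTable, label: str, split: Tuple[int, int], is_taxon: bool = False
) -> FoldChange:
    """Ratio of epoch-mean relative abundances (second epoch over first).

    Decreases are reported as factors > 1 with direction ``"decrease"``.
    Fold changes are computed on raw relative abundances (no pseudo-count).
    """
    n1, n2 = split
    if n1 + n2 != table.n_samples:
        raise ValidationError("split does not cover all samples")
    rel = table.relative_abundance()
    if is_taxon:
        per_sample, _, ids = taxon_relative_abundance(table, label)
        series = per_sample.to_numpy(float)
    else:
        if label not in rel.index:
            raise ValidationError(f"unknown OTU id {label!r}")
        series = rel.loc[label].to_numpy(float)
    m_high = series[:n1].mean()
    m_low = series[n1:].mean()
    if m_high == 0:
        return FoldChange(math.nan, "undefined")
    ratio = m_low / m_high
    if math.isclose(ratio, 1.0, rel_tol=0.0, abs_tol=1e-12):
        return FoldChange(1.0, "none")
    if ratio >= 1.0:
        return FoldChange(float(ratio), "increase")
    return FoldChange(float(1.0 / ratio), "decrease")


def ubiquitous_filter(table: OtuTable) -> pd.Index:
    """OTUs with nonzero counts in all samples — the only ones tested."""
    return table.counts.index[(table.counts > 0).all(axis=1)]


def epoch_change_table(
    table: OtuTable,
    split: Tuple[int, int],
    depth: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full change-point analysis: rarefy, normalise, test, correct.

    Returns a frame with columns ``otu_id, difference, f_statistic, p_raw,
    q, annotation`` sorted by q then p, covering the OTUs that pass the
    ubiquity filter (nonzero in every sample) after rarefaction.
    """
    n1, n2 = split
    if n1 + n2 != table.n_samples:
        raise ValidationError(
            f"split {split} incompatible with {table.n_samples} samples"
        )
    if depth is not None:
        table = rarefy(table, depth, seed)
    tested = ubiquitous_filter(table)
    if len(tested) == 0:
        raise ValidationError("no OTU passes the all-samples nonzero filter")
    norm = log_normalize(table).loc[tested]
    rows = []
    for otu in tested:
        r = step_change_test(norm.loc[otu].to_numpy(), split)
        rows.append((otu, r.difference, r.f_statistic, r.p_value))
    frame = pd.DataFrame(rows, columns=["otu_id", "difference", "f_statistic", "p_raw"])
    q, pi0 = qvalues(frame["p_raw"].to_numpy())
    frame["q"] = q
    frame["annotation"] = table.taxonomy.loc[frame["otu_id"]].to_numpy()
    frame.attrs["pi0"] = pi0
    frame.attrs["n_tested"] = len(tested)
    return frame.sort_values(["q", "p_raw"], kind="stable").reset_index(drop=True)


def simulate_error_rates(
    split: Tuple[int, int],
    effects: Sequence[float],
    rhos: Sequence[float],
    alpha: float = 0.05,
    reps: int = 10_000,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ErrorRateReport:
    """Rejection rate of the step test over an effect-size x AR(1) grid.

    Series of length n1+n2 are stationary AR(1) Gaussian noise (sd
    ``noise_sd``) with a mean step of ``effect`` after sample n1; effect 0
    rows measure the type-I error, rho > 0 rows its autocorrelation
    inflation.
    """
    n1, n2 = split
    n = n1 + n2
    rng = np.random.default_rng(seed)
    rows = []
    for rho in rhos:
        if not 0 <= rho < 1:
            raise ValidationError("ar1 rho must be in [0, 1)")
        for effect in effects:
            eps = rng.standard_normal((reps, n))
            x = np.empty((reps, n))
            x[:, 0] = eps[:, 0]
            for t in range(1, n):
                x[:, t] = rho * x[:, t - 1] + math.sqrt(1 - rho**2) * eps[:, t]
            x *= noise_sd
            x[:, n1:] += effect
            _, p = _step_test_batch(x, n1)
            rows.append((effect, rho, float(np.mean(p < alpha))))
    return ErrorRateReport(
        design=(n1, n2),
        alpha=alpha,
        reps=reps,
        rng_seed=seed,
        rates=pd.DataFrame(rows, columns=["effect", "rho", "rejection_rate"]),
    )
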