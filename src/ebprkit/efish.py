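"""In-silico FISH: exact IUPAC-aware probe matching in shotgun reads.

Oligonucleotide FISH probes (and PCR primers) designed against 16S rRNA
can be searched for directly in unassembled shotgun reads: a read "carries"
a probe if the probe sequence, or its reverse complement, occurs in the
read as an exact contiguous match, with degenerate IUPAC positions in the
probe matching any of their expansions.  Counting carrier reads per probe
and normalising to a universal bacterial probe (the EUB338 mix) gives a
sequence-based analogue of FISH quantification — subject to the usual
caveat that 16S copy-number differences are not corrected.

Probe *mixes* (EUBmix, PAOmix, GAOmix...) are aggregates: a mix counts the
distinct reads matching any of its member sequences.  No mismatches are
allowed by default; an optional single-substitution tolerance exists for
sensitivity analysis only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError, ValidationError

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_READ_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_probe(seq: str) -> str:
    s = str(seq).upper()
    if not s:
        raise ValidationError("empty probe sequence")
    bad = set(s) - set(IUPAC)
    if bad:
        raise ValidationError(f"non-IUPAC character(s) {sorted(bad)} in probe {s!r}")
    return s


def _pattern(seq: str) -> "re.Pattern[str]":
    """Regex matching the probe or its reverse complement in a concrete read."""
    def expand(s: str) -> str:
        return "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in s)

    return re.compile(f"(?:{expand(seq)})|(?:{expand(reverse_complement(seq))})")


@dataclass
class ProbeRecord:
    probe_id: str
    sequence: str
    target_group: str = ""
    role: str = "group_probe"  # group_probe | universal | primer

    def __post_init__(self) -> None:
        self.sequence = _validate_probe(self.sequence)
        if self.role not in ("group_probe", "universal", "primer"):
            raise ValidationError(f"unknown probe role {self.role!r}")


@dataclass
class ProbeSet:
    """Validated probe/primer records with one designated universal aggregate.

    ``mixes`` maps an aggregate name (e.g. ``PAOmix``) to its member probe
    ids; the universal reference may itself be a mix of several sequences.
    """

    records: List[ProbeRecord]
    mixes: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.probe_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("probe ids must be unique")
        by_id = {r.probe_id: r for r in self.records}
        for mix, members in self.mixes.items():
            missing = [m for m in members if m not in by_id]
            if missing:
                raise ConfigurationError(f"mix {mix!r} references unknown probe(s) {missing}")
        if not self.universal_ids:
            raise ConfigurationError("no universal probe designated")

    @property
    def universal_ids(self) -> List[str]:
        return [r.probe_id for r in self.records if r.role == "universal"]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class EfishCounts:
    """Raw and universal-normalised carrier-read counts for one sample.

    ``raw`` counts distinct reads with at least one match per probe (and
    per mix aggregate); ``normalized`` is raw / universal_hits, NaN and
    flagged when the universal probe hit nothing.
    """

    sample: str
    raw: Dict[str, int]
    universal_hits: int
    n_reads: int
    normalized: Dict[str, float] = field(default_factory=dict)
    undefined_normalization: bool = False


def iupac_match(probe: str, read: str, max_mismatches: int = 0) -> bool:
    """True iff the probe (or its reverse complement) occurs in the read.

    Degenerate probe positions match any of their IUPAC expansion; reads
    are concrete A/C/G/T, and an N in a read matches nothing.  The default
    is exact matching; ``max_mismatches=1`` enables a single-substitution
    tolerance for sensitivity analyses.
    """
    p = _validate_probe(probe)
    r = str(read).upper()
    bad = set(r) - _READ_ALPHABET
    if bad:
        raise ValidationError(f"invalid read character(s) {sorted(bad)}")
    if len(p) > len(r):
        raise ValidationError("probe longer than read")
    if max_mismatches == 0:
        return _pattern(p).search(r) is not None
    return _search_with_mismatches(p, r, max_mismatches)


def _search_with_mismatches(probe: str, read: str, k: int) -> bool:
    for query in (probe, reverse_complement(probe)):
        allowed = [set(IUPAC[c]) for c in query]
        m = len(query)
        for start in range(len(read) - m + 1):
            mism = 0
            for j in range(m):
                if read[start + j] not in allowed[j]:
                    mism += 1
                    if mism > k:
                        break
            if mism <= k:
                return True
    return False


def _as_sequences(reads: Iterable) -> List[str]:
    out = []
    for r in reads:
        if hasattr(r, "seq"):
            out.append(str(r.seq).upper())
        elif isinstance(r, (tuple, list)):
            out.append(str(r[1]).upper())
        else:
            out.append(str(r).upper())
    return out


def count_probe_hits(
    reads: Iterable, probes: ProbeSet, sample: str = "sample", max_mismatches: int = 0
) -> EfishCounts:
    """Carrier-read counts per probe and per mix over one read collection.

    A read matching two different probes increments both; a read matching
    one probe at several positions increments that probe once.  Mix
    aggregates count the distinct reads matching any member.
    """
    seqs = _as_sequences(reads)
    if not seqs or len(probes) == 0:
        raise ValidationError("need non-empty reads and probes")
    hit_masks: Dict[str, np.ndarray] = {}
    for rec in probes:
        if max_mismatches == 0:
            pat = _pattern(rec.sequence)
            mask = np.fromiter(
                (pat.search(s) is not None for s in seqs), bool, count=len(seqs)
            )
        else:
            mask = np.fromiter(
                (_search_with_mismatches(rec.sequence, s, max_mismatches) for s in seqs),
                bool,
                count=len(seqs),
            )
        hit_masks[rec.probe_id] = mask
    raw = {pid: int(m.sum()) for pid, m in hit_masks.items()}
    for mix, members in probes.mixes.items():
        agg = np.zeros(len(seqs), bool)
        for m in members:
            agg |= hit_masks[m]
        raw[mix] = int(agg.sum())
    uni = np.zeros(len(seqs), bool)
    for pid in probes.universal_ids:
        uni |= hit_masks[pid]
    return EfishCounts(
        sample=sample, raw=raw, universal_hits=int(uni.sum()), n_reads=len(seqs)
    )


def normalize_counts(counts: EfishCounts) -> EfishCounts:
    """Normalise raw carrier counts to the universal probe of the sample.

    A universal count of zero flags the sample rather than reporting
    silent zeros; the universal aggregate itself normalises to 1.
    """
    if counts.universal_hits == 0:
        counts.normalized = {pid: float("nan") for pid in counts.raw}
        counts.undefined_normalization = True
        return counts
    counts.normalized = {
        pid: hits / counts.universal_hits for pid, hits in counts.raw.items()
    }
    counts.undefined_normalization = False
    return counts
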