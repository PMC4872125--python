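"""IUPAC probe matching, carrier-read counting and universal normalisation."""

import math

import numpy as np
import pytest

from ebprkit.efish import (
    EfishCounts,
    ProbeRecord,
    ProbeSet,
    count_probe_hits,
    iupac_match,
    normalize_counts,
    reverse_complement,
)
from ebprkit.errors import ConfigurationError, InfeasibleSpecError, ValidationError
from ebprkit.simulate import ReadSimSpec, gen_reads_with_probes

UNIVERSAL = "GCTGCCTCCCGTAGGAGT"  # EUB338 target site
PAO_SITE = "CCCTCTGCCAAACTCCAG"


def probe_set(**kw):
    return ProbeSet(
        records=[
            ProbeRecord("EUB338", UNIVERSAL, role="universal"),
            ProbeRecord("PAO651", PAO_SITE, target_group="Accumulibacter"),
        ],
        **kw,
    )


class TestIupacMatch:
    def test_literal_substring(self):
        assert iupac_match("GCCTTC", "AAGCCTTCAA")

    def test_reverse_complement_detected(self):
        assert iupac_match("GCCTTC", "TTGAAGGCTT")

    @pytest.mark.parametrize(
        "read, expected",
        [("AAGCATTCAA", True), ("AAGCTTTCAA", True), ("AAGCGTTCAA", False)],
    )
    def test_degenerate_w_position(self, read, expected):
        assert iupac_match("GCWTTC", read) is expected

    def test_n_in_read_matches_nothing(self):
        assert not iupac_match("GCCTTC", "AAGCNTTCAA")

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            iupac_match("GCZTTC", "ACGT" * 5)
        with pytest.raises(ValidationError):
            iupac_match("ACGT", "ACXTACGT")

    def test_one_mismatch_mode_off_by_default(self):
        read = "AAAGCCTACAAA"  # one substitution inside the site
        assert not iupac_match("GCCTTC", read)
        assert iupac_match("GCCTTC", read, max_mismatches=1)


class TestProbeSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            ProbeSet(records=[ProbeRecord("a", "ACGT", role="universal"), ProbeRecord("a", "ACGT")])

    def test_universal_required(self):
        with pytest.raises(ConfigurationError):
            ProbeSet(records=[ProbeRecord("PAO651", PAO_SITE)])

    def test_degenerate_sequence_accepted(self):
        ProbeRecord("x", "ACWGT", role="universal")


class TestCounting:
    def test_every_read_carrying_site_counted_once(self):
        reads, _ = gen_reads_with_probes(
            ReadSimSpec(
                taxon_abundances={"PAO": 1.0},
                probe_sites={"PAO": {"PAO651": PAO_SITE}},
                universal_site=UNIVERSAL,
                n_reads=100,
                rng_seed=0,
            )
        )
        counts = count_probe_hits(reads, probe_set())
        assert counts.raw["PAO651"] == 100
        assert counts.universal_hits == 100

    def test_planted_carrier_fraction_recovered(self):
        n = 20_000
        reads, truth = gen_reads_with_probes(
            ReadSimSpec(
                taxon_abundances={"PAO": 0.05, "other": 0.95},
                probe_sites={"PAO": {"PAO651": PAO_SITE}},
                universal_site=UNIVERSAL,
                n_reads=n,
                rng_seed=4,
            )
        )
        counts = normalize_counts(count_probe_hits(reads, probe_set()))
        sigma = math.sqrt(n * 0.05 * 0.95)
        assert abs(counts.raw["PAO651"] - 0.05 * n) < 3 * sigma
        assert counts.normalized["PAO651"] == pytest.approx(0.05, abs=3 * sigma / n)

    def test_strand_symmetry(self):
        reads, _ = gen_reads_with_probes(
            ReadSimSpec(
                taxon_abundances={"PAO": 1.0},
                probe_sites={"PAO": {"PAO651": PAO_SITE}},
                universal_site=UNIVERSAL,
                n_reads=200,
                rng_seed=5,
            )
        )
        flipped = [(rid, reverse_complement(seq)) for rid, seq in reads]
        a = count_probe_hits(reads, probe_set())
        b = count_probe_hits(flipped, probe_set())
        assert a.raw == b.raw and a.universal_hits == b.universal_hits

    def test_order_independence(self):
        reads, _ = gen_reads_with_probes(
            ReadSimSpec(
                taxon_abundances={"PAO": 0.5, "other": 0.5},
                probe_sites={"PAO": {"PAO651": PAO_SITE}},
                universal_site=UNIVERSAL,
                n_reads=300,
                rng_seed=6,
            )
        )
        shuffled = list(reversed(reads))
        assert count_probe_hits(reads, probe_set()).raw == count_probe_hits(shuffled, probe_set()).raw

    def test_mix_counts_distinct_reads(self):
        # one read carries both members: the mix must count it once
        reads = [("r1", "A" * 10 + "GGGCCCTTTA" + "A" * 10 + "TTACGCGCGA" + "A" * 10),
                 ("r2", "C" * 40)]
        probes = ProbeSet(
            records=[
                ProbeRecord("u", "AAAAAAAAAA", role="universal"),
                ProbeRecord("m1", "GGGCCCTTTA"),
                ProbeRecord("m2", "TTACGCGCGA"),
            ],
            mixes={"mymix": ["m1", "m2"]},
        )
        counts = count_probe_hits(reads, probes)
        assert counts.raw["m1"] == 1 and counts.raw["m2"] == 1
        assert counts.raw["mymix"] == 1

    def test_non_detection_reported_as_zero(self):
        reads = [("r1", "A" * 50)]
        counts = count_probe_hits(reads, probe_set())
        assert counts.raw["PAO651"] == 0


class TestNormalisation:
    def test_simple_arithmetic(self):
        c = EfishCounts(sample="s", raw={"p": 50, "u": 1000}, universal_hits=1000, n_reads=2000)
        out = normalize_counts(c)
        assert out.normalized["p"] == pytest.approx(0.05)
        assert out.normalized["u"] == pytest.approx(1.0)

    def test_zero_universal_flags_not_zeroes(self):
        c = EfishCounts(sample="s", raw={"p": 5}, universal_hits=0, n_reads=10)
        out = normalize_counts(c)
        assert out.undefined_normalization
        assert math.isnan(out.normalized["p"])


class TestReadSimulation:
    def test_pure_function_of_spec(self):
        spec = ReadSimSpec(
            taxon_abundances={"PAO": 0.3, "other": 0.7},
            probe_sites={"PAO": {"PAO651": PAO_SITE}},
            universal_site=UNIVERSAL,
            n_reads=50,
            rng_seed=7,
        )
        assert gen_reads_with_probes(spec) == gen_reads_with_probes(spec)

    def test_forward_only_matching_misses_half_of_randomized_strands(self):
        n = 4000
        reads, _ = gen_reads_with_probes(
            ReadSimSpec(
                taxon_abundances={"PAO": 1.0},
                probe_sites={"PAO": {"PAO651": PAO_SITE}},
                universal_site="",
                universal_fraction=0.0,
                n_reads=n,
                randomize_strand=True,
                rng_seed=8,
            )
        )
        import re

        forward_only = sum(bool(re.search(PAO_SITE, seq)) for _, seq in reads)
        sigma = math.sqrt(n * 0.25)
        assert abs(forward_only - n / 2) < 4 * sigma

    def test_site_longer_than_read_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            ReadSimSpec(
                taxon_abundances={"x": 1.0},
                probe_sites={"x": {"p": "A" * 200}},
                read_length=150,
            )

    def test_bad_abundances_rejected(self):
        with pytest.raises(ValidationError):
            ReadSimSpec(taxon_abundances={"x": 0.5, "y": 0.4})
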