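import numpy as np
import pytest
from scipy import stats

import polreloc as pr
from polreloc.annotation import Bin, Interval
from polreloc.coverage import Peak
from polreloc.positional import (
    IUPAC,
    local_motif_enrichment,
    metagene_matrix,
    reverse_complement,
    scan_iupac,
    urs_poisson_enrichment,
)

MOTIF = "ACACCCAYACAYYY"


def brute_force_scan(seq, motif):
    """Position-by-position set-membership oracle (plus strand only)."""
    hits = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        win = seq[i : i + m]
        if all(b != "N" and b in IUPAC[c] for b, c in zip(win, motif)):
            hits.append(i)
    return hits


class TestScanIupac:
    def test_degenerate_position_matches(self):
        hits = scan_iupac("ACACCCATACATTT", MOTIF, both_strands=False)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (0, "+")

    def test_reverse_complement_hit(self):
        rc = reverse_complement("ACACCCATACATTT")
        hits = scan_iupac(rc, MOTIF)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].offset == 0

    def test_mismatch_at_degenerate_position(self):
        assert scan_iupac("ACACCCAGACATTT", MOTIF) == []

    def test_n_in_sequence_never_matches(self):
        assert scan_iupac("ACACCCANACATTT", MOTIF) == []

    def test_invalid_iupac_errors(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_iupac("ACGT", "AXGT")

    def test_agrees_with_brute_force_oracle_both_strands(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=3000))
            motif = ["ACAY", "RYYR", "ACWSGT"][trial % 3]
            got = {(h.offset, h.strand) for h in scan_iupac(seq, motif)}
            fwd = {(o, "+") for o in brute_force_scan(seq, motif)}
            m = len(motif)
            rev = {
                (len(seq) - o - m, "-")
                for o in brute_force_scan(reverse_complement(seq), motif)
            }
            assert got == fwd | rev


def _rp_setup(n_genes=20, chrom_len=500_000):
    genes = [
        pr.GeneModel(f"RP{i:03d}", pr.Interval("c", 20_000 * (i + 1),
                     20_000 * (i + 1) + 1500), "+", "mRNA", is_rp=True)
        for i in range(n_genes)
    ]
    ann = pr.GenomeAnnotation({"c": chrom_len}, genes)
    return ann, genes


class TestUrsPoissonEnrichment:
    def test_no_peaks_gives_p_one_everywhere(self):
        ann, genes = _rp_setup()
        out = urs_poisson_enrichment([], genes, ann)
        assert all(r.observed == 0 and r.pvalue == 1.0 for r in out)

    def test_poisson_tail_matches_direct_summation(self):
        # observed 30, expected 5: closed-form upper tail vs explicit sum
        import math

        term = math.exp(-5)
        for j in range(1, 31):
            term *= 5.0 / j
        direct, j = 0.0, 30
        while term > 1e-30:
            direct += term
            j += 1
            term *= 5.0 / j
        assert stats.poisson.sf(29, 5) == pytest.approx(direct, abs=1e-12)
        assert stats.poisson.sf(29, 5) == pytest.approx(2.3e-15, rel=0.1)

    def test_concentrated_peaks_flag_only_their_windows(self):
        ann, genes = _rp_setup()
        peaks = [
            Peak(interval=Interval("c", g.interval.start - 500,
                                   g.interval.start - 300))
            for g in genes
        ]
        out = urs_poisson_enrichment(peaks, genes, ann)
        sig = {r.window for r in out if r.fdr < 0.05}
        assert sig == {(-500, -400), (-400, -300)}
        assert all(r.stars == "***" for r in out if r.window in sig)

    def test_uniform_null_rarely_significant(self):
        ann, genes = _rp_setup()
        n_clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            starts = rng.integers(0, 499_000, size=40)
            peaks = [Peak(interval=Interval("c", int(s), int(s) + 600))
                     for s in starts]
            out = urs_poisson_enrichment(peaks, genes, ann)
            if not any(r.fdr < 0.05 for r in out):
                n_clean += 1
        assert n_clean >= 18


class TestLocalMotifEnrichment:
    def test_concentrated_hits_are_significant(self):
        rng = np.random.default_rng(9)
        offsets = (-300 + rng.integers(-20, 21, size=137)).tolist()
        res = local_motif_enrichment(offsets)
        assert res.pvalue < 1e-10
        assert res.window[0] <= -320 and res.window[1] >= -280

    def test_zero_hits(self):
        res = local_motif_enrichment([])
        assert res.pvalue == 1.0 and res.total_hits == 0

    def test_uniform_hits_rarely_significant(self):
        n_ns = 0
        for seed in range(20):
            rng = np.random.default_rng(50 + seed)
            offsets = rng.integers(-1000, 0, size=200).tolist()
            if local_motif_enrichment(offsets).pvalue > 0.05:
                n_ns += 1
        assert n_ns >= 18

    def test_binomial_tail_matches_direct_summation(self):
        n, k, p0 = 137, 60, 0.1
        direct = sum(
            stats.binom.pmf(j, n, p0) for j in range(k, n + 1)
        )
        assert stats.binom.sf(k - 1, n, p0) == pytest.approx(direct, abs=1e-12)


def _track_setup():
    bins = [Bin(Interval("c", i * 200, (i + 1) * 200), i) for i in range(100)]
    ann = pr.GenomeAnnotation(
        {"c": 20_000},
        [
            pr.GeneModel("G1", pr.Interval("c", 4_000, 6_000), "+", "mRNA"),
            pr.GeneModel("G2", pr.Interval("c", 10_000, 12_000), "-", "mRNA"),
        ],
    )
    return bins, ann


class TestMetageneMatrix:
    def test_uniform_track_gives_constant_matrix(self):
        bins, ann = _track_setup()
        mm = metagene_matrix(np.full(100, 3.0), bins, ann.genes, ann)
        assert np.allclose(mm.matrix, 3.0)
        assert mm.matrix.shape == (2, 5 + 100)

    def test_rows_sorted_by_descending_signal(self):
        bins, ann = _track_setup()
        track = np.zeros(100)
        track[20:30] = 5.0   # G1 body
        track[50:60] = 10.0  # G2 body
        mm = metagene_matrix(track, bins, ann.genes, ann)
        assert mm.gene_ids == ["G2", "G1"]

    def test_minus_strand_orientation_flip(self):
        bins, ann = _track_setup()
        # ramp rising toward G2's TSS (TSS at 12000, minus strand)
        track = np.zeros(100)
        track[50:60] = np.arange(10, dtype=float)  # rises toward 12000
        mm = metagene_matrix(track, bins, ann.genes, ann)
        row = mm.matrix[mm.gene_ids.index("G2")]
        body = row[5:]
        # after the flip the body should *fall* away from the TSS column
        assert body[0] > body[-1]
        assert np.all(np.diff(body) <= 1e-9)

    def test_linearity_in_the_track(self):
        bins, ann = _track_setup()
        rng = np.random.default_rng(10)
        track = rng.uniform(0, 5, 100)
        m1 = metagene_matrix(track, bins, ann.genes, ann).matrix
        m3 = metagene_matrix(3 * track, bins, ann.genes, ann).matrix
        np.testing.assert_allclose(m3, 3 * m1, rtol=1e-12)

    def test_tie_broken_by_gene_id(self):
        bins, ann = _track_setup()
        mm = metagene_matrix(np.zeros(100), bins, ann.genes, ann)
        assert mm.gene_ids == ["G1", "G2"]
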