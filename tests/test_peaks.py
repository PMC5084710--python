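import math

import numpy as np
import pytest

import apexkit as ak
from apexkit.peaks import (
    ConsensusRegion,
    GeneModel,
    PeakCall,
    read_gene_models,
    read_narrowpeak,
    write_gff3,
    write_narrowpeak,
)


def P(chrom, start, end, q=10.0, rep=""):
    return PeakCall(chrom=chrom, start=start, end=end, neg_log10_q=q, replicate_id=rep)


def mask_oracle(treatment, controls, L, q_max=1e-3, min_overlap=50):
    """Per-base AND of replicate coverage masks (oracle)."""
    nlq = -math.log10(q_max)
    cov = np.ones(L, bool)
    for reps in treatment:
        m = np.zeros(L, bool)
        for p in reps:
            if p.neg_log10_q >= nlq - 1e-9:
                m[p.start : p.end] = True
        cov &= m
    ctrl = np.zeros(L, bool)
    for reps in controls:
        for p in reps:
            ctrl[p.start : p.end] = True
    out = []
    i = 0
    while i < L:
        if cov[i]:
            j = i
            while j < L and cov[j]:
                j += 1
            if j - i >= min_overlap and not ctrl[i:j].any():
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestConsensus:
    def test_three_replicate_intersection(self):
        t = [[P("c", 100, 300)], [P("c", 150, 350)], [P("c", 180, 400)]]
        regions = ak.consensus_regions(t, [[], [], []])
        assert [(r.start, r.end) for r in regions] == [(180, 300)]
        assert regions[0].length == 120

    def test_short_overlap_rejected(self):
        t = [[P("c", 100, 300)], [P("c", 150, 350)], [P("c", 270, 400)]]
        assert ak.consensus_regions(t, [[], [], []]) == []

    def test_control_overlap_rejected(self):
        t = [[P("c", 100, 300)], [P("c", 150, 350)], [P("c", 180, 400)]]
        ctl = [[P("c", 250, 260, q=0.5)], [], []]
        assert ak.consensus_regions(t, ctl) == []

    def test_q_threshold_applied_per_replicate(self):
        t = [[P("c", 100, 300, q=2.9)], [P("c", 150, 350)], [P("c", 180, 400)]]
        assert ak.consensus_regions(t, [[], [], []]) == []
        t[0][0] = P("c", 100, 300, q=3.0)  # q = 1e-3 passes "1e-3 or lower"
        assert len(ak.consensus_regions(t, [[], [], []])) == 1

    def test_matches_per_base_mask_oracle_on_random_toys(self):
        rng = np.random.default_rng(12)
        L = 100_000
        for _ in range(25):
            treatment = []
            for _ in range(3):
                starts = np.sort(rng.integers(0, L - 400, size=30))
                treatment.append(
                    [
                        P("c", int(s), int(s + rng.integers(60, 400)), q=float(rng.uniform(0, 30)))
                        for s in starts
                    ]
                )
            controls = []
            for _ in range(3):
                starts = rng.integers(0, L - 300, size=8)
                controls.append([P("c", int(s), int(s + 200), q=1.0) for s in starts])
            got = [(r.start, r.end) for r in ak.consensus_regions(treatment, controls)]
            assert got == mask_oracle(treatment, controls, L)

    def test_every_region_covered_by_each_replicate_and_no_control(self, toy_genome_sim):
        sim = toy_genome_sim
        regions = ak.consensus_regions(sim.treatment, sim.controls)
        assert regions
        for r in regions:
            for reps in sim.treatment:
                assert any(
                    p.chrom == r.chrom and p.start <= r.start and p.end >= r.end
                    for p in reps
                    if p.neg_log10_q >= 3
                )
            for reps in sim.controls:
                assert not any(
                    p.chrom == r.chrom and p.start < r.end and p.end > r.start for p in reps
                )

    def test_non_three_replicates_unsupported_rule_raises(self):
        with pytest.raises(NotImplementedError):
            ak.consensus_regions([[P("c", 0, 100)]], [[]], n_required=0)


def G(gene_id, cds, strand="+", chrom="c", tx=None):
    tx = tx or (cds[0] - 50, cds[1] + 50)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        cds_start=cds[0], cds_end=cds[1],
        transcript_start=tx[0], transcript_end=tx[1],
    )


def region_at(center, chrom="c"):
    return ConsensusRegion(chrom=chrom, start=center - 30, end=center + 30)


class TestAssignment:
    def test_upstream_window_plus_strand(self):
        g = [G("g1", (10_000, 12_000))]
        hit = ak.assign_to_genes([region_at(8_000)], g)  # 2 kb upstream
        assert list(hit.gene_id) == ["g1"]
        assert hit.iloc[0].relation == "upstream"
        miss = ak.assign_to_genes([region_at(6_500)], g)  # 3.5 kb upstream
        assert miss.empty

    def test_window_bounds_are_exactly_3000_and_1500(self):
        g = [G("g1", (10_000, 12_000))]
        assert not ak.assign_to_genes([region_at(7_000)], g).empty  # exactly 3 kb
        assert ak.assign_to_genes([region_at(6_999)], g).empty
        assert not ak.assign_to_genes([region_at(13_499)], g).empty  # within 1.5 kb
        assert ak.assign_to_genes([region_at(13_500)], g).empty

    def test_strand_awareness_swaps_the_windows(self):
        g = [G("g1", (10_000, 12_000), strand="-")]
        # 5' of a minus-strand CDS is to the right: 3 kb window there
        assert not ak.assign_to_genes([region_at(14_500)], g).empty
        assert ak.assign_to_genes([region_at(14_500)], [G("g1", (10_000, 12_000))]).empty
        # left side only 1.5 kb for minus strand
        assert not ak.assign_to_genes([region_at(8_600)], g).empty
        assert ak.assign_to_genes([region_at(8_400)], g).empty

    def test_intervening_cds_blocks_attribution(self):
        g_target = G("target", (10_000, 12_000))
        g_blocker = G("blocker", (8_300, 9_200))
        center = 8_000  # 2 kb upstream of target, blocker fully between
        alone = ak.assign_to_genes([region_at(center)], [g_target])
        both = ak.assign_to_genes([region_at(center)], [g_target, g_blocker])
        assert list(alone.gene_id) == ["target"]
        assert "target" not in set(both.gene_id)
        assert "blocker" in set(both.gene_id)  # still attributed to the near gene

    def test_region_may_serve_two_flanking_genes(self):
        left = G("left", (2_000, 4_000))    # center 1.4 kb downstream of left
        right = G("right", (7_000, 9_000))  # and 1.6 kb upstream of right
        hits = ak.assign_to_genes([region_at(5_400)], [left, right])
        assert set(hits.gene_id) == {"left", "right"}

    def test_reverse_complement_symmetry(self, toy_genome_sim):
        sim = toy_genome_sim
        regions = ak.consensus_regions(sim.treatment, sim.controls)
        table = ak.assign_to_genes(regions, sim.genes)
        L = sim.params.chrom_length
        flip = {"+": "-", "-": "+"}
        rc_genes = [
            GeneModel(
                gene_id=g.gene_id, chrom=g.chrom, strand=flip[g.strand],
                cds_start=L - g.cds_end, cds_end=L - g.cds_start,
                transcript_start=L - g.transcript_end, transcript_end=L - g.transcript_start,
            )
            for g in sim.genes
        ]
        rc_regions = [
            ConsensusRegion(chrom=r.chrom, start=L - r.end, end=L - r.start) for r in regions
        ]
        rc_table = ak.assign_to_genes(rc_regions, rc_genes)
        key = lambda df: sorted(zip(df.chrom, df.gene_id, df.relation))
        # same gene attributions with the same upstream/downstream relations
        assert key(table) == key(rc_table)


class TestEnrichment:
    def test_single_region_in_transcribed_span(self):
        g = [G("g1", (10_000, 12_000), tx=(9_900, 12_100))]
        res = ak.positional_enrichment([region_at(11_000)], g, n_sims=200, seed=0)
        assert res.statistic == 0
        assert res.p_value == 1.0

    def test_p_floor_is_one_over_sims_plus_one(self):
        g = [G("g1", (10_000, 12_000))]
        regions = [region_at(7_500 + 37 * i) for i in range(40)]  # all in the promoter
        res = ak.positional_enrichment(regions, g, n_sims=1000, seed=0)
        assert res.p_value >= 1 / 1001
        assert res.p_value == pytest.approx(1 / 1001)

    def test_seeded_runs_reproducible(self):
        g = [G("g1", (10_000, 12_000))]
        regions = [region_at(8_000), region_at(11_000)]
        r1 = ak.positional_enrichment(regions, g, n_sims=300, seed=7)
        r2 = ak.positional_enrichment(regions, g, n_sims=300, seed=7)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_statistics, r2.null_statistics)

    def test_zero_regions_rejected(self):
        with pytest.raises(ValueError):
            ak.positional_enrichment([], [G("g1", (10_000, 12_000))], n_sims=200)

    def test_planted_promoter_bias_recovered(self):
        sim = ak.generate_genome_and_peaks(
            ak.GenomeSimParams(seed=31, zone_probs={"promoter": 1.0, "transcribed": 0.0, "downstream": 0.0})
        )
        regions = ak.consensus_regions(sim.treatment, sim.controls)
        res = ak.positional_enrichment(regions, sim.genes, n_sims=10_000, seed=1, compute_histogram=False)
        assert res.p_value <= 1e-3


class TestMotifExport:
    def test_observed_and_control_counts_and_width(self, toy_genome_sim, tmp_path):
        sim = toy_genome_sim
        paths = sim.write(tmp_path / "sim")
        regions = ak.consensus_regions(sim.treatment, sim.controls)[:3]
        obs, ctl = tmp_path / "obs.fa", tmp_path / "ctl.fa"
        n_obs, n_ctl = ak.export_motif_sequences(regions, paths["fasta"], obs, ctl, seed=0)
        assert (n_obs, n_ctl) == (3, 30)
        from pyfaidx import Fasta

        recs = Fasta(str(obs))
        assert all(len(recs[k]) == 151 for k in recs.keys())

    def test_fixed_seed_gives_byte_identical_control_files(self, toy_genome_sim, tmp_path):
        sim = toy_genome_sim
        paths = sim.write(tmp_path / "sim")
        regions = ak.consensus_regions(sim.treatment, sim.controls)[:2]
        files = []
        for i in (1, 2):
            obs, ctl = tmp_path / f"o{i}.fa", tmp_path / f"c{i}.fa"
            ak.export_motif_sequences(regions, paths["fasta"], obs, ctl, seed=42)
            files.append(ctl.read_bytes())
        assert files[0] == files[1]

    def test_degenerate_half_width_zero(self, toy_genome_sim, tmp_path):
        sim = toy_genome_sim
        paths = sim.write(tmp_path / "sim")
        regions = ak.consensus_regions(sim.treatment, sim.controls)[:1]
        obs, ctl = tmp_path / "o.fa", tmp_path / "c.fa"
        ak.export_motif_sequences(regions, paths["fasta"], obs, ctl, half_width=0, seed=0)
        lines = obs.read_text().splitlines()
        assert len(lines[1]) == 1

    def test_window_clipped_at_chromosome_start(self, toy_genome_sim, tmp_path):
        sim = toy_genome_sim
        paths = sim.write(tmp_path / "sim")
        edge = [ConsensusRegion(chrom="chr1", start=0, end=20)]
        obs, ctl = tmp_path / "o.fa", tmp_path / "c.fa"
        ak.export_motif_sequences(edge, paths["fasta"], obs, ctl, seed=0)
        assert len(obs.read_text().splitlines()[1]) == 10 + 76  # clipped left side


def hypergeom_oracle_p(n11, n10, n01, n00):
    """Fisher two-sided p by hypergeometric enumeration (oracle)."""
    from scipy.stats import hypergeom

    N = n11 + n10 + n01 + n00
    K = n11 + n10  # size of set a
    n = n11 + n01  # size of set b
    probs = np.array([hypergeom.pmf(k, N, K, n) for k in range(max(0, K + n - N), min(K, n) + 1)])
    obs = hypergeom.pmf(n11, N, K, n)
    return probs[probs <= obs * (1 + 1e-9)].sum()


class TestFisher:
    def test_disjoint_halves_maximal_depletion(self):
        universe = [f"g{i}" for i in range(20)]
        a, b = universe[:10], universe[10:]
        odds, p = ak.overlap_fisher(a, b, universe)
        assert odds == 0.0
        assert p == pytest.approx(hypergeom_oracle_p(0, 10, 10, 0), rel=1e-9)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(40)]
        for _ in range(20):
            a = list(rng.choice(universe, size=rng.integers(5, 25), replace=False))
            b = list(rng.choice(universe, size=rng.integers(5, 25), replace=False))
            _, p = ak.overlap_fisher(a, b, universe)
            sa, sb = set(a), set(b)
            n11 = len(sa & sb)
            n10 = len(sa - sb)
            n01 = len(sb - sa)
            n00 = 40 - n11 - n10 - n01
            assert p == pytest.approx(hypergeom_oracle_p(n11, n10, n01, n00), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ak.overlap_fisher([], [], [])

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ak.overlap_fisher(["x"], [], ["a", "b"])


class TestFormatIO:
    def test_narrowpeak_round_trip(self, tmp_path):
        peaks = [
            PeakCall(chrom="chr1", start=10, end=260, neg_log10_q=5.5, fold_enrichment=3.2,
                     summit_offset=120, name="p1"),
            PeakCall(chrom="chr2", start=0, end=90, neg_log10_q=12.0, fold_enrichment=8.0,
                     summit_offset=45, name="p2"),
        ]
        path = tmp_path / "x.narrowPeak"
        write_narrowpeak(peaks, path)
        back = read_narrowpeak(path, replicate_id="r")
        assert [(p.chrom, p.start, p.end, p.neg_log10_q, p.name) for p in back] == [
            ("chr1", 10, 260, 5.5, "p1"),
            ("chr2", 0, 90, 12.0, "p2"),
        ]

    def test_gff3_round_trip_converts_coordinates(self, tmp_path):
        genes = [
            G("gA", (1_000, 2_000), strand="+", tx=(900, 2_100)),
            G("gB", (5_000, 6_000), strand="-", tx=(4_950, 6_050)),
        ]
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        back = read_gene_models(path)
        assert [(g.gene_id, g.cds_start, g.cds_end, g.strand, g.transcript_start) for g in back] == [
            ("gA", 1_000, 2_000, "+", 900),
            ("gB", 5_000, 6_000, "-", 4_950),
        ]
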