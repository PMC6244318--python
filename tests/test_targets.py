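"""Seed extraction, site scanning, complementarity alignment, target calls."""

import numpy as np
import pytest

from rfinet.targets import (
    AlignmentParams,
    align_mirna_utr,
    extract_seed,
    normalize_nt,
    predict_targets,
    reverse_complement,
    scan_seed_sites,
    SeedSite,
    AlignmentHit,
)

RNA = list("ACGU")
DNA = list("ACGT")


class TestExtractSeed:
    def test_positions_two_to_eight(self):
        assert extract_seed("UAGCUUAUCAGACUGAUGUUGA") == "AGCTTAT"

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("UAGCUUA")

    def test_u_t_normalization_idempotent(self):
        assert extract_seed("TAGCTTATCAGACTGATGTTGA") == extract_seed(
            "UAGCUUAUCAGACUGAUGUUGA"
        )


def _oracle_scan(mirna, utr):
    """Independent site scan: direct string comparison at every offset."""
    mir = normalize_nt(mirna)
    utr = normalize_nt(utr)
    six = reverse_complement(mir[1:7])
    seven_m8 = reverse_complement(mir[1:8])
    sites = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != six:
            continue
        m8 = i >= 1 and utr[i - 1 : i + 6] == seven_m8
        a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if m8 and a1:
            sites.append(SeedSite(i - 1, i + 7, "8mer"))
        elif m8:
            sites.append(SeedSite(i - 1, i + 6, "7mer-m8"))
        elif a1:
            sites.append(SeedSite(i, i + 7, "7mer-A1"))
        else:
            sites.append(SeedSite(i, i + 6, "6mer"))
    return sites


class TestScanSeedSites:
    def test_constructed_8mer(self, rng):
        mir = "".join(rng.choice(RNA, 22))
        utr = "CG" + reverse_complement(normalize_nt(mir)[1:8]) + "A" + "CG"
        sites = scan_seed_sites(mir, utr)
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0] == SeedSite(2, 10, "8mer")

    def test_no_complementarity_empty(self):
        # seed core of this miRNA is CCCCCC; an all-A UTR cannot contain it
        mir = "AGGGGGGGGGGGGGGGGGGGGG"
        assert scan_seed_sites(mir, "A" * 50) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mir = "".join(rng.choice(RNA, 22))
        utr = "".join(rng.choice(DNA, 5000))
        # plant a few sites so matches are guaranteed sometimes
        core = reverse_complement(normalize_nt(mir)[1:8]) + "A"
        pos = rng.integers(0, 4990, size=3)
        utr_list = list(utr)
        for p in pos:
            utr_list[p : p + 8] = core
        utr = "".join(utr_list)
        assert scan_seed_sites(mir, utr) == _oracle_scan(mir, utr)

    def test_site_type_hierarchy_and_exclusive_labels(self, rng):
        """Each seed-core locus is reported once, at its most specific class."""
        mir = "".join(rng.choice(RNA, 22))
        utr = "".join(rng.choice(DNA, 5000))
        core6 = reverse_complement(normalize_nt(mir)[1:7])
        m8 = reverse_complement(normalize_nt(mir)[7])
        sites = scan_seed_sites(mir, utr)
        n_cores = utr.count(core6)  # non-overlapping count is enough here
        assert len(sites) >= n_cores > 0 or n_cores == 0
        for s in sites:
            frag = utr[s.start : s.end]
            if s.site_type == "8mer":
                assert frag == m8 + core6 + "A"
            elif s.site_type == "7mer-m8":
                assert frag == m8 + core6
                assert s.end >= len(utr) or utr[s.end] != "A"
            elif s.site_type == "7mer-A1":
                assert frag == core6 + "A"
                assert s.start == 0 or utr[s.start - 1] != m8
            else:
                assert frag == core6
                assert s.start == 0 or utr[s.start - 1] != m8
                assert s.end >= len(utr) or utr[s.end] != "A"

    def test_short_utr_rejected(self):
        with pytest.raises(ValueError):
            scan_seed_sites("UAGCUUAUCAGACUGAUGUUGA", "ACGT")


def _oracle_sw(q, d, weights, p: AlignmentParams):
    """Independent affine-gap local alignment, plain recursive formulation."""
    import functools

    n, m = len(q), len(d)

    def score(i, j):
        qc, dc = q[i], d[j]
        pair = {qc, dc}
        if pair in ({"A", "T"}, {"C", "G"}) and qc != dc:
            s = p.match
        elif pair == {"G", "T"}:
            s = p.wobble
        else:
            s = p.mismatch
        return s * weights[i]

    @functools.lru_cache(maxsize=None)
    def H(i, j):
        if i == 0 or j == 0:
            return 0.0
        return max(0.0, H(i - 1, j - 1) + score(i - 1, j - 1), E(i, j), F(i, j))

    @functools.lru_cache(maxsize=None)
    def E(i, j):
        if j == 0:
            return -1e18
        return max(H(i, j - 1) + p.gap_open, E(i, j - 1) + p.gap_extend)

    @functools.lru_cache(maxsize=None)
    def F(i, j):
        if i == 0:
            return -1e18
        return max(H(i - 1, j) + p.gap_open, F(i - 1, j) + p.gap_extend)

    return max(H(i, j) for i in range(n + 1) for j in range(m + 1))


class TestAlignment:
    def test_perfect_revcomp_score(self, rng):
        mir = "".join(rng.choice(RNA, 22))
        hits = align_mirna_utr(mir, reverse_complement(mir))
        assert len(hits) == 1
        # 15 plain matches * 5 + 7 seed matches * 5 * 2
        assert hits[0].score == pytest.approx(145.0)

    def test_zero_complementarity_no_hits(self):
        assert align_mirna_utr("A" * 22, "A" * 40) == []

    def test_empty_sequences(self):
        assert align_mirna_utr("", "ACGT") == []
        assert align_mirna_utr("ACGU" * 6, "") == []

    @pytest.mark.parametrize("seed", range(30))
    def test_optimal_score_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        mir = "".join(rng.choice(RNA, rng.integers(10, 30)))
        utr = "".join(rng.choice(DNA, 30))
        params = AlignmentParams(score_threshold=1.0)
        hits = align_mirna_utr(mir, utr, params)
        q = normalize_nt(mir)[::-1]
        L = len(q)
        weights = [
            params.seed_weight if 2 <= L - r <= 8 else 1.0 for r in range(L)
        ]
        best = _oracle_sw(q, normalize_nt(utr), tuple(weights), params)
        if best >= params.score_threshold:
            assert hits, "oracle finds a hit above threshold"
            assert hits[0].score == pytest.approx(best)
        else:
            assert hits == []

    def test_non_overlapping_hits(self, rng):
        mir = "".join(rng.choice(RNA, 22))
        site = reverse_complement(mir)
        utr = site + "".join(rng.choice(DNA, 30)) + site
        hits = align_mirna_utr(mir, utr)
        assert len(hits) == 2
        spans = sorted((h.utr_start, h.utr_end) for h in hits)
        assert spans[0][1] <= spans[1][0]


class TestPredictTargets:
    def test_both_evidence_types_retained(self):
        seeds = {("m1", "g1"): [SeedSite(0, 6, "6mer")]}
        aligns = {("m1", "g1"): [AlignmentHit(90.0, 0, 20, "x", "y")]}
        ts = predict_targets(seeds, aligns, {"g1"})
        assert ts.genes("m1") == ["g1"]

    def test_empty_universe_empty_output(self):
        seeds = {("m1", "g1"): [SeedSite(0, 6, "6mer")]}
        aligns = {("m1", "g1"): [AlignmentHit(90.0, 0, 20, "x", "y")]}
        ts = predict_targets(seeds, aligns, set())
        assert ts.pairs() == set()

    @pytest.mark.parametrize("mode", ["intersection", "union"])
    def test_matches_set_algebra_oracle(self, rng, mode):
        mirnas = [f"m{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(20)]
        seeds, aligns = {}, {}
        for m in mirnas:
            for g in genes:
                if rng.random() < 0.3:
                    seeds[(m, g)] = [SeedSite(0, 6, "6mer")]
                if rng.random() < 0.3:
                    aligns[(m, g)] = [AlignmentHit(85.0, 0, 10, "x", "y")]
        expressed = set(rng.choice(genes, size=10, replace=False))
        ts = predict_targets(seeds, aligns, expressed, mode=mode)
        s_pairs, a_pairs = set(seeds), set(aligns)
        expected = s_pairs & a_pairs if mode == "intersection" else s_pairs | a_pairs
        expected = {(m, g) for m, g in expected if g in expressed}
        assert ts.pairs() == expected

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            predict_targets({}, {}, {"g"}, mode="both")


class TestSequenceProperties:
    from hypothesis import given, settings, strategies as st

    nt = st.text(alphabet="ACGU", min_size=8, max_size=30)

    @given(nt)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == normalize_nt(seq)

    @given(nt, st.text(alphabet="ACGT", min_size=6, max_size=60))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_scan_agrees_with_oracle(self, mir, utr):
        assert scan_seed_sites(mir, utr) == _oracle_scan(mir, utr)
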