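"""PWM scanning, enrichment, redundancy collapse, co-occurrence, spacing."""

import math

import numpy as np
import pandas as pd
import pytest

from photoclose.motifs import (
    Pwm,
    central_density_profile,
    collapse_redundant,
    consensus_pwm,
    cooccurrence,
    hit_presence,
    motif_enrichment,
    pwm_similarity,
    read_motifs,
    sample_matched_background,
    scan,
    spacing_profile,
    trim_low_info,
    write_motifs,
)
from photoclose.seqs import BASES, revcomp


def brute_force_scan(seq: str, pwm: Pwm, threshold: float):
    """Per-position rescoring oracle, both strands, natural-log odds."""
    probs = pwm.smoothed()
    hits = []
    for strand in ("+", "-"):
        mat = probs if strand == "+" else probs[::-1, ::-1]
        for off in range(len(seq) - pwm.width + 1):
            score = 0.0
            for j, base in enumerate(seq[off : off + pwm.width]):
                if base in BASES:
                    score += math.log(mat[j, BASES.index(base)] / 0.25)
            if score >= threshold:
                hits.append((off, strand, round(score, 9)))
    return sorted(hits)


def random_pwm(rng, width, name="m"):
    m = rng.dirichlet(np.ones(4), size=width)
    return Pwm(name, m)


class TestScan:
    def test_uniform_pwm_hits_everywhere(self):
        pwm = Pwm("u", np.full((4, 4), 0.25))
        hits = scan({"s": "ACGTACGT"}, pwm, threshold=0.0)
        # 5 offsets x 2 strands, all scoring ~0
        assert len(hits) == 10
        assert all(abs(h.score) < 1e-9 for h in hits)

    def test_consensus_pwm_hits_exact_matches_only(self):
        pwm = consensus_pwm("crx", "CTAATCC")
        seq = "GGGG" + "CTAATCC" + "AAAA" + revcomp("CTAATCC") + "TT"
        hits = scan({"s": seq}, pwm, threshold=0.8 * pwm.max_score())
        assert {(h.offset, h.strand) for h in hits} == {(4, "+"), (15, "-")}

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            pwm = random_pwm(rng, int(rng.integers(4, 9)))
            seq = "".join(rng.choice(list("ACGTN"), 80, p=[0.24] * 4 + [0.04]))
            got = sorted(
                (h.offset, h.strand, round(h.score, 9))
                for h in scan({"s": seq}, pwm, threshold=-1.0)
            )
            assert got == brute_force_scan(seq, pwm, -1.0)

    def test_strand_symmetry(self, rng):
        pwm = random_pwm(rng, 6)
        seqs = {"a": "ACGTTGCAACGTGGTAC", "b": "TTTTACGTACCCGG"}
        fwd = {(h.seq_id, h.strand, round(h.score, 6)) for h in scan(seqs, pwm, -2)}
        rc = {
            (h.seq_id, h.strand, round(h.score, 6))
            for h in scan({k: revcomp(v) for k, v in seqs.items()}, pwm, -2)
        }
        flip = {("+", "-"): None}
        mirrored = {(s, "+" if st == "-" else "-", sc) for s, st, sc in rc}
        assert fwd == mirrored

    def test_n_positions_score_as_background(self):
        pwm = consensus_pwm("m", "ACGT")
        (h_plus,) = [h for h in scan({"s": "ACGN"}, pwm, threshold=-10) if h.strand == "+"]
        (h_full,) = [h for h in scan({"s": "ACGT"}, pwm, threshold=1) if h.strand == "+"]
        # N contributes zero: score is exactly the 3-base partial sum
        assert h_plus.score < h_full.score
        assert h_plus.score == pytest.approx(h_full.score * 3 / 4, rel=0.01)


class TestMotifIO:
    def test_round_trip(self, tmp_path, rng):
        lib = [random_pwm(rng, w, f"m{w}") for w in (4, 6, 9)]
        for m in lib:
            m.log_odds_threshold = 5.0
        path = tmp_path / "motifs.txt"
        write_motifs(path, lib)
        back = read_motifs(path)
        assert [m.name for m in back] == [m.name for m in lib]
        for a, b in zip(lib, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)
            assert b.log_odds_threshold == 5.0


class TestTrim:
    def test_uniform_flanks_removed(self):
        core = consensus_pwm("m", "ACGT").matrix
        flank = np.full((2, 4), 0.25)
        pwm = Pwm("m", np.vstack([flank, core, flank]))
        trimmed = trim_low_info(pwm)
        assert trimmed.width == 4
        assert np.allclose(trimmed.matrix, core)

    def test_all_consensus_is_identity(self):
        pwm = consensus_pwm("m", "ACGTA")
        assert trim_low_info(pwm).width == 5

    def test_exactly_one_bit_kept(self):
        # p = (0.5, 0.5, 0, 0) has exactly 1 bit; strict "<" keeps it
        col = np.array([[0.5, 0.5, 0.0, 0.0]])
        pwm = Pwm("m", np.vstack([col, consensus_pwm("x", "ACG").matrix]))
        assert trim_low_info(pwm, 1.0).width == 4

    def test_all_trimmed_is_error(self):
        with pytest.raises(ValueError):
            trim_low_info(Pwm("m", np.full((3, 4), 0.25)))


class TestCollapse:
    def test_exact_duplicate_absorbed(self, rng):
        a = random_pwm(rng, 8, "a")
        dup = Pwm("dup", a.matrix.copy())
        seeds, mapping = collapse_redundant([a, dup], {"a": 2.0, "dup": 1.0})
        assert [m.name for m in seeds] == ["a"]
        assert mapping == {"a": "a", "dup": "a"}

    def test_reverse_complement_absorbed(self, rng):
        a = random_pwm(rng, 8, "a")
        rc = Pwm("rc", a.reverse_complement().matrix)
        seeds, mapping = collapse_redundant([a, rc], {"a": 2.0, "rc": 1.0})
        assert mapping["rc"] == "a"

    def test_matches_exhaustive_oracle(self, rng):
        lib = [random_pwm(rng, int(rng.integers(5, 10)), f"m{i}") for i in range(12)]
        scores = {m.name: float(rng.random()) for m in lib}
        seeds, mapping = collapse_redundant(lib, scores, pcc_threshold=0.6)
        # oracle: same greedy definition, written independently over the
        # full pairwise similarity matrix
        order = sorted(lib, key=lambda m: (-scores[m.name], m.name))
        sim = {
            (x.name, y.name): pwm_similarity(x, y) for x in lib for y in lib
        }
        expect_map = {}
        expect_seeds = []
        for m in order:
            if m.name in expect_map:
                continue
            expect_seeds.append(m.name)
            expect_map[m.name] = m.name
            for other in order:
                if other.name not in expect_map and sim[(m.name, other.name)] > 0.6:
                    expect_map[other.name] = m.name
        assert [m.name for m in seeds] == expect_seeds
        assert mapping == expect_map

    def test_every_motif_maps_to_one_seed(self, rng):
        lib = [random_pwm(rng, 6, f"m{i}") for i in range(20)]
        seeds, mapping = collapse_redundant(lib)
        assert set(mapping) == {m.name for m in lib}
        assert len(seeds) <= len(lib)
        seed_names = {m.name for m in seeds}
        assert set(mapping.values()) <= seed_names


class TestCooccurrence:
    @staticmethod
    def presence_frame(n, spec):
        df = pd.DataFrame(False, index=range(n), columns=list(spec))
        for motif, idx in spec.items():
            df.loc[list(idx), motif] = True
        return df

    def test_independence_case_closed_form(self):
        # N=100, n1=50, n2=20, O=10 -> E=10, enrichment 0
        df = self.presence_frame(
            100, {"m1": range(50), "m2": list(range(40, 50)) + list(range(90, 100))}
        )
        co = cooccurrence(df)
        assert co.expected[0, 1] == pytest.approx(10.0)
        assert co.observed[0, 1] == 10
        assert co.enrichment[0, 1] == pytest.approx(0.0)

    def test_twofold_case(self):
        # O=20 with same margins -> enrichment log2(2) = 1
        df = self.presence_frame(
            100, {"m1": range(50), "m2": range(30, 50)}
        )
        co = cooccurrence(df)
        assert co.observed[0, 1] == 20
        assert co.enrichment[0, 1] == pytest.approx(1.0)

    def test_zero_observed_is_neg_inf(self):
        df = self.presence_frame(10, {"m1": range(5), "m2": range(5, 10)})
        co = cooccurrence(df)
        assert np.isneginf(co.enrichment[0, 1])

    def test_independent_planting_null(self):
        rng = np.random.default_rng(42)
        n = 10_000
        df = pd.DataFrame(
            {
                "a": rng.random(n) < 0.3,
                "b": rng.random(n) < 0.2,
                "c": rng.random(n) < 0.5,
            }
        )
        co = cooccurrence(df)
        off = co.enrichment[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) <= 0.2)

    def test_symmetry_and_bounds(self, rng):
        df = pd.DataFrame(rng.random((500, 4)) < 0.3, columns=list("abcd"))
        co = cooccurrence(df)
        assert np.allclose(co.observed, co.observed.T)
        for i in range(4):
            for j in range(4):
                assert co.observed[i, j] <= min(co.per_motif[i], co.per_motif[j])


class TestBackground:
    def test_same_distribution_matches_quickly(self, rng):
        from photoclose.simulate import markov_sequence

        genome = {"chr1": markov_sequence(200_000, rng)}
        targets = [
            genome["chr1"][i : i + 200] for i in rng.integers(0, 199_800, 50)
        ]
        bg, meta = sample_matched_background(
            genome, targets, n=100, length=200, rng=rng
        )
        assert len(bg) == 100
        assert meta["achieved_l1"] <= 0.05

    def test_biased_targets_shift_composition(self, rng):
        from photoclose.seqs import mono_di_frequencies
        from photoclose.simulate import markov_sequence

        genome = {"chr1": markov_sequence(300_000, rng, gc=0.40)}
        # GC-rich synthetic targets
        targets = [
            "".join(rng.choice(list("ACGT"), 200, p=[0.15, 0.35, 0.35, 0.15]))
            for _ in range(50)
        ]
        # an extreme GC gap cannot reach tolerance from a uniform pool;
        # assert the resampling moves composition toward the target and
        # reports the best-achieved distance
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            bg, meta = sample_matched_background(
                genome, targets, n=150, length=200, rng=rng, max_iter=20000
            )
        pool_freq = mono_di_frequencies(
            [genome["chr1"][i : i + 200] for i in range(0, 299_800, 200)]
        )
        bg_freq = mono_di_frequencies(bg)
        assert bg_freq[1] + bg_freq[2] > pool_freq[1] + pool_freq[2] + 0.01
        assert meta["achieved_l1"] < 1.5

    def test_too_many_windows_requested(self, rng):
        genome = {"chr1": "ACGT" * 300}
        with pytest.raises(ValueError):
            sample_matched_background(genome, ["ACGT" * 50], n=1000, length=200, rng=rng)


class TestProfiles:
    def test_planted_central_motif_spikes_at_center(self):
        pwm = consensus_pwm("m", "CTAATCCG")
        flank = "A" * 96
        seqs = {f"s{i}": flank + "CTAATCCG" + flank for i in range(10)}
        prof = central_density_profile(seqs, pwm, threshold=0.8 * pwm.max_score())
        peak_bin = prof.loc[prof["density"].idxmax()]
        assert abs(peak_bin["position"]) <= 5
        assert peak_bin["density"] == pytest.approx(1.0)

    def test_no_hits_gives_zero_profile(self):
        pwm = consensus_pwm("m", "CTAATCCG")
        prof = central_density_profile(
            {"s": "A" * 200}, pwm, threshold=0.8 * pwm.max_score()
        )
        assert (prof["density"] == 0).all()

    def test_unequal_widths_rejected(self):
        pwm = consensus_pwm("m", "ACGT")
        with pytest.raises(ValueError):
            central_density_profile({"a": "ACGT" * 10, "b": "ACGT" * 9}, pwm)


class TestSpacing:
    def test_fixed_offset_same_strand_spike(self):
        prim = consensus_pwm("p", "CTAATCC")
        sec = consensus_pwm("s", "AGGTCA")
        # secondary always 3 bp downstream of the primary's end
        seqs = {
            f"s{i}": "G" * 20 + "CTAATCC" + "TTT" + "AGGTCA" + "G" * 20
            for i in range(8)
        }
        prof = spacing_profile(
            seqs, prim, sec,
            threshold=0.8 * sec.max_score(),
            primary_threshold=0.8 * prim.max_score(),
        )
        top = prof.loc[prof["count"].idxmax()]
        assert top["offset"] == 10  # 7 bp motif + 3 bp gap
        assert top["relative_strand"] == "same"
        assert top["count"] == 8

    def test_self_pair_masks_zero_offset(self):
        pwm = consensus_pwm("p", "CTAATCCG")
        seqs = {"s": "A" * 20 + "CTAATCCG" + "A" * 20}
        prof = spacing_profile(
            seqs, pwm, pwm,
            threshold=0.8 * pwm.max_score(),
            primary_threshold=0.8 * pwm.max_score(),
        )
        assert prof.empty or (prof["offset"] != 0).all()

    def test_no_primary_hits_warns_empty(self):
        prim = consensus_pwm("p", "CTAATCCG")
        sec = consensus_pwm("s", "AGGTCA")
        with pytest.warns(UserWarning, match="no primary hits"):
            prof = spacing_profile({"s": "A" * 50}, prim, sec, threshold=5)
        assert prof.empty


class TestEnrichmentWorkflow:
    def test_planted_motif_ranks_first(self, rng):
        from photoclose.simulate import markov_sequence, plant_motif

        lib = [consensus_pwm("planted", "TGCTGACTCAGCA"), consensus_pwm("other", "CATATG")]
        targets = {}
        for i in range(40):
            s = markov_sequence(200, rng)
            targets[f"t{i}"] = plant_motif(s, lib[0], 90, "+")
        background = {f"b{i}": markov_sequence(200, rng) for i in range(200)}
        table = motif_enrichment(targets, background, lib, threshold=5.0)
        assert table.iloc[0]["motif"] == "planted"
        assert table.iloc[0]["ratio"] > 2
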