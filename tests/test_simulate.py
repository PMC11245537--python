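"""Synthetic data generators: determinism, digestion rules, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abseqmap.features import gene_usage, jaccard_overlap, light_chain_coherence_within
from abseqmap.simulate import (
    DigestConfig,
    SimulationConfig,
    back_translate,
    cleavage_sites,
    default_germline,
    digest,
    generate_contaminants,
    generate_decoy_reference,
    simulate_abseq_run,
    simulate_paired_repertoire,
    simulate_repertoire,
    subsample_replicates,
)
from abseqmap.core import translate_nt

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
protein_strategy = st.text(alphabet=PROTEIN_ALPHABET, min_size=1, max_size=60)


class TestSimulateRepertoire:
    def test_seeded_runs_identical(self, heavy_germline):
        cfg = SimulationConfig(n_clonotypes=300, seed=7)
        g1 = default_germline("heavy")
        g2 = default_germline("heavy")
        r1 = simulate_repertoire(cfg, g1, donor="Dx")
        r2 = simulate_repertoire(SimulationConfig(n_clonotypes=300, seed=7), g2, donor="Dx")
        assert [(c.clonotype_key, c.size, c.vdj_aa) for c in r1.clonotypes] == [
            (c.clonotype_key, c.size, c.vdj_aa) for c in r2.clonotypes
        ]

    def test_degenerate_usage_concentrates_on_one_gene(self):
        g = default_germline("heavy", n_v=5)
        probs = np.zeros(5)
        probs[2] = 1.0
        g.v_usage["Dz"] = probs
        cfg = SimulationConfig(n_clonotypes=50, seed=3)
        rep = simulate_repertoire(cfg, g, donor="Dz")
        assert {c.v_gene for c in rep.clonotypes} == {g.v_genes[2][0]}

    def test_cdr3_anchors_and_span(self, base_config, heavy_germline):
        rep = simulate_repertoire(base_config, heavy_germline, donor="Da")
        for ct in rep.clonotypes[:50]:
            assert ct.cdr3_aa[0] == "C" and ct.cdr3_aa[-1] == "W"
            s, e = ct.cdr3_span
            assert ct.vdj_aa[s:e] == ct.cdr3_aa
            assert translate_nt(ct.cdr3_nt) == ct.cdr3_aa

    def test_strong_expansion_drives_evenness_down(self, heavy_germline):
        """A steep rank-size law concentrates mass in the top clone, and the
        evenness at high alpha approaches 1/(n * max f) computed directly."""
        from abseqmap.features import evenness_profile

        cfg = SimulationConfig(n_clonotypes=100, clone_size_zipf_exponent=3.0, seed=5)
        rep = simulate_repertoire(cfg, heavy_germline, donor="Db")
        f = np.array(rep.frequencies())
        prof = evenness_profile(rep, alpha_grid=[10.0])
        direct = (np.sum(f**10.0)) ** (1 / (1 - 10.0)) / rep.n
        assert prof.E_values[0] == pytest.approx(direct)
        assert prof.E_values[0] < 0.2

    def test_n_clonotypes_must_be_positive(self, heavy_germline):
        with pytest.raises(ValueError):
            simulate_repertoire(
                SimulationConfig(n_clonotypes=0, seed=1), heavy_germline
            )

    def test_gene_usage_recovery_at_scale(self):
        """Realised usage of a 10^4-clonotype repertoire correlates >= 0.99
        with the configured per-donor usage distribution."""
        g = default_germline("heavy")
        cfg = SimulationConfig(n_clonotypes=10_000, seed=21)
        rep = simulate_repertoire(cfg, g, donor="Dr")
        prof = gene_usage(rep)
        configured = g.v_usage["Dr"]
        realised = np.array(
            [prof.frequencies.get(name, 0.0) for name, _ in g.v_genes]
        )
        r = np.corrcoef(configured, realised)[0, 1]
        assert r >= 0.99

    def test_inter_donor_sharing_near_zero_without_shared_pool(self):
        g = default_germline("heavy")
        cfg = SimulationConfig(n_clonotypes=10_000, seed=31)
        a = simulate_repertoire(cfg, g, donor="Du")
        b = simulate_repertoire(cfg, g, donor="Dv")
        assert jaccard_overlap(a.cdr3_set(), b.cdr3_set()) < 1e-3

    def test_shared_pool_produces_overlap(self):
        g = default_germline("heavy")
        pool_cfg = SimulationConfig(n_clonotypes=500, seed=41)
        pool = simulate_repertoire(pool_cfg, g, donor="Dpool").clonotypes
        cfg = SimulationConfig(n_clonotypes=500, donor_overlap=0.3, seed=42)
        a = simulate_repertoire(cfg, g, donor="Dw", shared_pool=pool)
        b = simulate_repertoire(cfg, g, donor="Dxx", shared_pool=pool)
        assert jaccard_overlap(a.cdr3_set(), b.cdr3_set()) > 0.01


class TestPairedRepertoire:
    def test_rho_one_gives_full_coherence(self, heavy_germline, light_germline):
        cfg = SimulationConfig(n_clonotypes=100, light_chain_coherence=1.0, seed=17)
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=200
        )
        res = light_chain_coherence_within(sc)
        assert res.n_eligible_pairs > 0
        assert res.coherence_pct == 100.0

    def test_rho_zero_near_chance_level(self):
        """With rho=0 the second cell's light V is an independent draw from
        the light-gene usage distribution, so pair coherence sits at the
        Sum(q_v^2)-style collision baseline, far below 50%."""
        hg = default_germline("heavy")
        lg = default_germline("kappa", n_v=25)
        cfg = SimulationConfig(
            n_clonotypes=2000, light_chain_coherence=0.0, paired_fraction=1.0, seed=19
        )
        sc = simulate_paired_repertoire(cfg, hg, lg, donor="Dz0", n_cells=4000)
        res = light_chain_coherence_within(sc)
        q = lg.v_usage["Dz0"]
        chance_pct = 100 * float(np.sum(q**2))
        assert res.n_eligible_pairs >= 1000
        assert res.coherence_pct < 50
        se = 100 * np.sqrt(chance_pct / 100 * (1 - chance_pct / 100) / res.n_eligible_pairs)
        assert abs(res.coherence_pct - chance_pct) < 5 * se + 2

    def test_rho_recovery_within_five_points(self, heavy_germline, light_germline):
        cfg = SimulationConfig(
            n_clonotypes=1000, light_chain_coherence=0.9, paired_fraction=1.0, seed=23
        )
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=1000
        )
        res = light_chain_coherence_within(sc)
        assert res.n_eligible_pairs >= 200
        assert abs(res.coherence_pct - 90.0) <= 5.0

    def test_eligible_pairs_have_distinct_nt(self, heavy_germline, light_germline):
        cfg = SimulationConfig(n_clonotypes=100, seed=29, paired_fraction=1.0)
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=100
        )
        groups = {}
        for cell in sc.cells:
            groups.setdefault(
                (cell.heavy.v_gene, cell.heavy.cdr3_aa), []
            ).append(cell.heavy)
        multi = [g for g in groups.values() if len(g) > 1]
        assert multi
        for g in multi:
            keys = {h.clonotype_key for h in g}
            assert len(keys) == len(g)
            assert len({h.cdr3_aa for h in g}) == 1


class TestSubsampleReplicates:
    def test_exact_depth_and_count(self, heavy_germline, light_germline):
        cfg = SimulationConfig(n_clonotypes=100, seed=37)
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=500
        )
        reps = subsample_replicates(sc, k=8, depth=100, seed=1)
        assert len(reps) == 8
        assert all(len(r.cells) == 100 for r in reps)
        assert len({r.replicate_id for r in reps}) == 8

    def test_full_depth_single_replicate_equals_parent(
        self, heavy_germline, light_germline
    ):
        cfg = SimulationConfig(n_clonotypes=50, seed=43)
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=80
        )
        (rep,) = subsample_replicates(sc, k=1, depth=80, seed=2)
        assert {c.cell_id.split(":", 1)[1] for c in rep.cells} == {
            c.cell_id for c in sc.cells
        }
        assert rep.cdr3_set() == sc.cdr3_set()

    def test_union_of_cdrh3_non_decreasing_in_k(
        self, heavy_germline, light_germline
    ):
        cfg = SimulationConfig(n_clonotypes=100, seed=47)
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=300
        )
        reps = subsample_replicates(sc, k=5, depth=60, seed=3)
        union = set()
        sizes = []
        for r in reps:
            union |= r.cdr3_set()
            sizes.append(len(union))
        assert sizes == sorted(sizes)

    def test_depth_beyond_cells_errors(self, heavy_germline, light_germline):
        cfg = SimulationConfig(n_clonotypes=20, seed=53)
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, n_cells=30
        )
        with pytest.raises(ValueError):
            subsample_replicates(sc, k=2, depth=31, seed=4)


def brute_force_peptides(protein, protease, max_missed, min_len, max_len):
    """Oracle: enumerate fragments between sites, then all adjacent windows."""
    sites = cleavage_sites(protein, protease)
    bounds = [0] + sites + [len(protein)]
    frags = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    out = set()
    for i in range(len(frags)):
        for m in range(max_missed + 1):
            if i + m >= len(frags):
                break
            start, end = frags[i][0], frags[i + m][1]
            if min_len <= end - start <= max_len:
                out.add((protein[start:end], start, end, m))
    return out


class TestDigest:
    def test_trypsin_hand_example(self):
        cfg = DigestConfig("trypsin", max_missed_cleavages=0, min_length=1)
        assert [p.sequence for p in digest("PEPTIDEKARTW", cfg)] == ["PEPTIDEK", "AR", "TW"]

    def test_trypsin_not_before_proline(self):
        cfg = DigestConfig("trypsin", max_missed_cleavages=0, min_length=1)
        assert [p.sequence for p in digest("AKPLR", cfg)] == ["AKPLR"]

    def test_chymotrypsin_high_specificity(self):
        cfg = DigestConfig("chymotrypsin", max_missed_cleavages=0, min_length=1)
        # cleaves after F/W/Y, blocked before P; L and M are not sites
        assert [p.sequence for p in digest("AAFGLWPMY", cfg)] == ["AAF", "GLWPMY"]

    def test_aspn_cleaves_before_aspartate(self):
        cfg = DigestConfig("aspn", max_missed_cleavages=0, min_length=1)
        assert [p.sequence for p in digest("AADGGDK", cfg)] == ["AA", "DGG", "DK"]

    def test_combined_digest_is_union_of_sites(self):
        protein = "AKFGDWRM"
        both = set(cleavage_sites(protein, "chymotrypsin_then_trypsin"))
        assert both == set(cleavage_sites(protein, "trypsin")) | set(
            cleavage_sites(protein, "chymotrypsin")
        )

    @pytest.mark.parametrize(
        "protease", ["trypsin", "chymotrypsin", "chymotrypsin_then_trypsin", "aspn"]
    )
    @given(protein=protein_strategy)
    @settings(max_examples=60, deadline=None)
    def test_zero_missed_peptides_partition_protein(self, protease, protein):
        cfg = DigestConfig(protease, max_missed_cleavages=0, min_length=1,
                           max_length=10_000)
        peps = digest(protein, cfg)
        assert "".join(p.sequence for p in peps) == protein
        pos = 0
        for p in peps:
            assert (p.start, p.end) == (pos, pos + len(p.sequence))
            pos = p.end

    @pytest.mark.parametrize(
        "protease", ["trypsin", "chymotrypsin", "chymotrypsin_then_trypsin", "aspn"]
    )
    @given(protein=protein_strategy, max_missed=st.integers(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_missed_cleavage_windows_match_oracle(self, protease, protein, max_missed):
        cfg = DigestConfig(protease, max_missed_cleavages=max_missed,
                           min_length=1, max_length=10_000)
        got = {(p.sequence, p.start, p.end, p.missed_cleavages)
               for p in digest(protein, cfg)}
        assert got == brute_force_peptides(protein, protease, max_missed, 1, 10_000)

    def test_length_filter_applied(self):
        cfg = DigestConfig("trypsin", max_missed_cleavages=2, min_length=7, max_length=40)
        for p in digest("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", cfg):
            assert 7 <= len(p.sequence) <= 40

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            digest("ACDX", DigestConfig("trypsin"))

    def test_agrees_with_pyteomics_cleave(self):
        """Independent oracle: pyteomics' cleavage enumeration for trypsin."""
        from pyteomics import parser as mqparser

        protein = "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGE"
        for mc in (0, 1, 2):
            ours = {
                p.sequence
                for p in digest(
                    protein,
                    DigestConfig("trypsin", max_missed_cleavages=mc,
                                 min_length=1, max_length=10_000),
                )
            }
            theirs = mqparser.cleave(
                protein, rule=mqparser.expasy_rules["trypsin"], missed_cleavages=mc,
                min_length=1,
            )
            assert ours == set(theirs)


class TestAbseqRun:
    @pytest.fixture
    def references(self, heavy_germline, light_germline):
        cfg = SimulationConfig(n_clonotypes=200, seed=61, n_serum_clonotypes=20)
        bulk = simulate_repertoire(cfg, heavy_germline, donor="Dm")
        sc = simulate_paired_repertoire(
            cfg, heavy_germline, light_germline, donor="Dm", n_cells=100
        )
        return cfg, bulk, sc

    def test_clean_run_all_peptides_from_references(self, references):
        cfg, bulk, sc = references
        table = simulate_abseq_run([bulk, sc], cfg)
        assert len(table) > 0
        keys = {ct.clonotype_key for r in (bulk, sc) for ct in r.clonotypes}
        assert set(table["true_source"]).issubset(keys)

    def test_trypsin_zero_missed_peptides_tile_source(
        self, heavy_germline, light_germline
    ):
        cfg = SimulationConfig(n_clonotypes=60, seed=67, n_serum_clonotypes=50)
        bulk = simulate_repertoire(cfg, heavy_germline, donor="Dt")
        dcfg = DigestConfig("trypsin", max_missed_cleavages=0, min_length=1,
                            max_length=10_000)
        table = simulate_abseq_run([bulk], cfg, digests=[dcfg])
        by_key = {ct.clonotype_key: ct for ct in bulk.clonotypes}
        for key, sub in table.groupby("true_source"):
            sub = sub.sort_values("start")
            assert sub.iloc[0]["start"] == 0
            assert sub.iloc[-1]["end"] == len(by_key[key].vdj_aa)
            rebuilt = "".join(sub["sequence"])
            assert rebuilt == by_key[key].vdj_aa

    def test_determinism(self, references):
        cfg, bulk, sc = references
        t1 = simulate_abseq_run([bulk, sc], cfg)
        t2 = simulate_abseq_run([bulk, sc], cfg)
        assert t1.equals(t2)

    def test_empty_reference_errors(self, references):
        cfg, _, _ = references
        with pytest.raises(ValueError):
            simulate_abseq_run([], cfg)

    def test_contaminant_and_decoy_labels(self, references, heavy_germline):
        cfg, bulk, sc = references
        cfg2 = SimulationConfig(
            n_clonotypes=200, seed=61, n_serum_clonotypes=20,
            contaminant_rate=0.1, decoy_rate=0.1,
        )
        decoys = generate_decoy_reference(
            50, heavy_germline, seed=3,
            true_sequences={ct.vdj_aa for r in (bulk, sc) for ct in r.clonotypes},
        )
        table = simulate_abseq_run(
            [bulk, sc], cfg2, contaminants=generate_contaminants(), decoys=decoys
        )
        assert (table["true_source"] == "contaminant").sum() > 0
        assert (table["true_source"] == "decoy").sum() > 0


class TestDecoys:
    def test_zero_decoys(self, heavy_germline):
        assert generate_decoy_reference(0, heavy_germline, seed=1) == []

    def test_disjoint_from_true_reference(self, heavy_germline):
        cfg = SimulationConfig(n_clonotypes=300, seed=71)
        rep = simulate_repertoire(cfg, heavy_germline, donor="Dd")
        true_seqs = {ct.vdj_aa for ct in rep.clonotypes}
        decoys = generate_decoy_reference(500, heavy_germline, seed=5,
                                          true_sequences=true_seqs)
        assert len(decoys) == 500
        assert not (set(decoys) & true_seqs)

    def test_large_count(self, heavy_germline):
        decoys = generate_decoy_reference(10_000, heavy_germline, seed=9)
        assert len(decoys) == 10_000


class TestBackTranslate:
    def test_canonical_is_deterministic_and_consistent(self):
        aa = "CARDSW"
        nt = back_translate(aa)
        assert back_translate(aa) == nt
        assert translate_nt(nt) == aa

    def test_randomised_codons_still_translate_back(self):
        rng = np.random.default_rng(0)
        aa = "CSSLW"
        variants = {back_translate(aa, rng) for _ in range(20)}
        assert len(variants) > 1
        for v in variants:
            assert translate_nt(v) == aa
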