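"""Panel extraction, NJ correctness, and origin-classification rules."""

import numpy as np
import pandas as pd
import pytest

from svorigin import introgression as intro
from svorigin import variant_io as vio
from svorigin.synthetic import (
    CohortConfig,
    cohort_to_matrices,
    inject_introgression,
    random_cattle_to_yak_events,
    simulate_cohort,
)
from conftest import random_tree_distances


@pytest.fixture(scope="module")
def snp_sv_popmap():
    cfg = CohortConfig(
        n_wild_yak=4, n_domestic_yak=4, n_cattle=4, n_outgroup=1,
        n_snps_per_window=80, n_sv_loci=2, seed=31,
    )
    cohort = simulate_cohort(cfg)
    snp, sv = cohort_to_matrices(cohort)
    return snp, sv, dict(cohort.populations), cfg


class TestExtractFlankingHaplotypes:
    def test_window_boundaries(self, snp_sv_popmap):
        snp, sv, popmap, cfg = snp_sv_popmap
        record = sv.variants.iloc[0]
        panel = intro.extract_flanking_haplotypes(
            snp, record, sv.genotypes[0], popmap,
            intro.ClassifierConfig(window_bp=10_000),
        )
        lo, hi = record["pos"] - 10_000, record["pos"] + 10_000
        assert ((panel.positions >= lo) & (panel.positions <= hi)).all()
        # only SNPs on the SV's own contig are collected
        on_chrom = snp.variants["chrom"] == record["chrom"]
        in_win = on_chrom & snp.variants["pos"].between(lo, hi)
        assert panel.n_sites == int(in_win.sum())

    def test_deletion_masks_snps_on_carrier_haplotypes(self, snp_sv_popmap):
        snp, sv, popmap, _ = snp_sv_popmap
        record = sv.variants.iloc[0].copy()
        record["svtype"], record["svlen"] = "DEL", 2_000
        panel = intro.extract_flanking_haplotypes(
            snp, record, sv.genotypes[0], popmap
        )
        inside = (panel.positions > record["pos"]) & (
            panel.positions <= record["pos"] + 2_000
        )
        carriers = panel.sv_alleles > 0
        assert inside.any() and carriers.any()
        assert (panel.sequences[np.ix_(carriers, inside)] == -1).all()
        assert (panel.sequences[np.ix_(~carriers, inside)] >= 0).all()

    def test_no_snps_in_window_yields_empty_panel(self, snp_sv_popmap):
        snp, sv, popmap, _ = snp_sv_popmap
        record = sv.variants.iloc[0].copy()
        record["chrom"] = "nowhere"
        panel = intro.extract_flanking_haplotypes(snp, record, sv.genotypes[0], popmap)
        assert panel.n_sites == 0
        result = intro.classify_panel(panel)
        assert result.flag == "no_snps" and result.direction == "none"

    def test_unphased_window_raises(self, snp_sv_popmap):
        snp, sv, popmap, _ = snp_sv_popmap
        unphased = vio.GenotypeMatrix(
            samples=list(snp.samples),
            variants=snp.variants,
            genotypes=snp.genotypes,
            phased=np.zeros_like(snp.phased),
        )
        with pytest.raises(intro.ClassificationError, match="unphased"):
            intro.extract_flanking_haplotypes(
                unphased, sv.variants.iloc[0], sv.genotypes[0], popmap
            )


class TestTaggingSNPs:
    def test_planted_r2_selection(self):
        """Exactly the planted high-LD SNPs survive; oracle recomputes r2."""
        rng = np.random.default_rng(8)
        n_haps = 40
        sv = (np.arange(n_haps) < 20).astype(np.int8)
        cols = []
        for j in range(20):
            if j < 7:  # perfectly coupled to the SV allele
                cols.append(sv.copy())
            else:  # independent noise
                cols.append(rng.integers(0, 2, n_haps).astype(np.int8))
        seqs = np.stack(cols, axis=1)
        panel = intro.HaplotypePanel(
            sv_id="sv", positions=np.arange(1, 21), sequences=seqs,
            samples=[f"s{i//2}" for i in range(n_haps)],
            hap_index=np.tile([0, 1], n_haps // 2),
            populations=np.array(["domestic_yak"] * n_haps, dtype=object),
            sv_alleles=sv,
        )
        from svorigin.divergence import ld_r2

        expected = [
            j for j in range(20)
            if (r2 := ld_r2(seqs[:, j], sv)) == r2 and r2 >= 0.45
        ]
        _, kept = intro.select_tagging_snps(panel)
        assert kept.tolist() == expected
        assert set(range(7)) <= set(kept)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = intro.nj_tree(d, ["A", "B", "C"])
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_four_taxon_recovery(self):
        # ((A,B),(C,D)) with internal edge 3
        d = np.array(
            [
                [0, 2, 7, 8],
                [2, 0, 7, 8],
                [7, 7, 0, 3],
                [8, 8, 3, 0],
            ],
            dtype=float,
        )
        tree = intro.nj_tree(d, list("ABCD"))
        assert tree.bipartitions() == {frozenset({"A", "B"})}

    def test_all_zero_matrix_star_with_zero_lengths(self):
        tree = intro.nj_tree(np.zeros((4, 4)), list("ABCD"))
        assert sorted(tree.leaf_names()) == list("ABCD")
        for leaf in tree.leaves():
            assert leaf.length == 0.0

    def test_validation_errors(self):
        with pytest.raises(intro.ClassificationError):
            intro.nj_tree(np.zeros((2, 2)), ["A", "B"])
        bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(intro.ClassificationError):
            intro.nj_tree(bad, list("ABC"))

    def test_random_additive_recovery_small(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            dist, labels, true_splits = random_tree_distances(n, rng)
            tree = intro.nj_tree(dist, labels)
            assert tree.bipartitions() == true_splits

    def test_agrees_with_scikit_bio_on_random_matrices(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        for _ in range(5):
            n = 8
            raw = rng.uniform(1, 5, size=(n, n))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0)
            labels = [f"t{i}" for i in range(n)]
            mine = intro.nj_tree(d, labels).bipartitions()
            ref_tree = skbio_nj(DistanceMatrix(d, labels))
            all_leaves = frozenset(labels)
            theirs = set()
            for node in ref_tree.non_tips(include_self=False):
                names = frozenset(t.name for t in node.tips())
                if 1 < len(names) < n - 1:
                    theirs.add(min(names, all_leaves - names, key=sorted))
            assert mine == theirs


def _toy_tree(newick_spec):
    """Build a small rooted tree from nested tuples: (children...) or name."""
    def build(spec):
        if isinstance(spec, str):
            return intro.Clade(name=spec, length=1.0)
        node = intro.Clade(length=1.0)
        for child in spec:
            node.add(build(child))
        return node

    root = build(newick_spec)
    root.length = 0.0
    return root


class TestClassifyHaplotypeOrigin:
    CFG = intro.ClassifierConfig()

    def test_yak_query_in_cattle_clade_is_cattle_derived(self):
        root = _toy_tree(((("q", "c1", "c2", "c3"), ("w1", "w2", "w3")), "og"))
        pops = {"q": "domestic_yak", "c1": "cattle", "c2": "cattle",
                "c3": "cattle", "w1": "wild_yak", "w2": "wild_yak",
                "w3": "wild_yak", "og": "outgroup"}
        origin, n_ref, purity = intro.classify_haplotype_origin(root, "q", pops, self.CFG)
        assert origin == "cattle_derived" and n_ref == 3 and purity == 1.0

    def test_yak_query_among_wild_yaks_is_native(self):
        root = _toy_tree(((("q", "w1", "w2", "w3", "w4", "w5"),
                          ("c1", "c2", "c3")), "og"))
        pops = {"q": "domestic_yak", "og": "outgroup"}
        pops.update({f"w{i}": "wild_yak" for i in range(1, 6)})
        pops.update({f"c{i}": "cattle" for i in range(1, 4)})
        origin, n_ref, _ = intro.classify_haplotype_origin(root, "q", pops, self.CFG)
        assert origin == "native" and n_ref == 5

    def test_mixed_clade_below_purity_is_unclassified(self):
        root = _toy_tree(((("q", "c1", "c2", "w1", "w2"), ("w3", "w4", "w5")), "og"))
        pops = {"q": "domestic_yak", "og": "outgroup",
                "c1": "cattle", "c2": "cattle"}
        pops.update({f"w{i}": "wild_yak" for i in range(1, 6)})
        origin, n_ref, purity = intro.classify_haplotype_origin(root, "q", pops, self.CFG)
        assert origin == "unclassified" and n_ref == 4 and purity == 0.5

    def test_cattle_query_in_yak_clade_is_yak_derived(self):
        root = _toy_tree(((("q", "w1", "w2", "w3"), ("c1", "c2", "c3")), "og"))
        pops = {"q": "cattle", "og": "outgroup"}
        pops.update({f"w{i}": "wild_yak" for i in range(1, 4)})
        pops.update({f"c{i}": "cattle" for i in range(1, 4)})
        origin, _, _ = intro.classify_haplotype_origin(root, "q", pops, self.CFG)
        assert origin == "yak_derived"


class TestClassifySVOrigin:
    def _call(self, pop, origin):
        return intro.HaplotypeCall("s", 0, pop, origin, 3, 1.0)

    def test_direction_rules(self):
        c2y = [self._call("domestic_yak", "cattle_derived"),
               self._call("domestic_yak", "native"),
               self._call("cattle", "native")]
        assert intro.classify_sv_origin(c2y) == "cattle_to_yak"
        mutual = c2y + [self._call("cattle", "yak_derived")]
        assert intro.classify_sv_origin(mutual) == "mutual"
        y2c = [self._call("cattle", "yak_derived"), self._call("domestic_yak", "native")]
        assert intro.classify_sv_origin(y2c) == "yak_to_cattle"
        assert intro.classify_sv_origin([self._call("cattle", "native")]) == "none"


class TestCohortSummary:
    def test_fractions(self):
        popmap = {f"y{i}": "domestic_yak" for i in range(10)}
        popmap["c1"] = "cattle"
        calls = [
            intro.SVOriginCall(
                "sv0", "cattle_to_yak",
                [intro.HaplotypeCall("y0", 0, "domestic_yak", "cattle_derived", 3, 1.0)],
                10,
            )
        ]
        per_sample, fraction = intro.cohort_introgression_summary(calls, popmap)
        assert per_sample["y0"] == 1 and fraction == pytest.approx(0.1)

    def test_no_calls_zero_fraction(self):
        popmap = {"y0": "domestic_yak"}
        _, fraction = intro.cohort_introgression_summary([], popmap)
        assert fraction == 0.0


class TestEndToEndSmall:
    def test_recovery_and_order_invariance(self):
        """Planted events are recovered, and calls are invariant to sample
        order in the panel (classification does not depend on input order)."""
        cfg = CohortConfig(
            n_wild_yak=6, n_domestic_yak=8, n_cattle=6, n_outgroup=2,
            n_snps_per_window=300, n_sv_loci=6, seed=41,
        )
        cohort = simulate_cohort(cfg)
        events = random_cattle_to_yak_events(cohort, sv_fraction=0.5, seed=42)
        cohort, truth = inject_introgression(cohort, events, seed=43)
        panels = intro.panels_from_cohort(cohort)
        results = {p.sv_id: intro.classify_panel(p) for p in panels}

        truth_dirs = truth.groupby("sv_index")["direction"].first()
        for sv_index, want in truth_dirs.items():
            assert results[f"sv{sv_index}"].direction == want

        # permute haplotype rows of one event panel: same calls per haplotype
        event_sv = events[0].sv_index
        panel = panels[event_sv]
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_haps)
        shuffled = intro.HaplotypePanel(
            sv_id=panel.sv_id,
            positions=panel.positions,
            sequences=panel.sequences[perm],
            samples=[panel.samples[i] for i in perm],
            hap_index=panel.hap_index[perm],
            populations=panel.populations[perm],
            sv_alleles=panel.sv_alleles[perm],
        )
        base = results[f"sv{event_sv}"].calls_frame().set_index(["sample", "hap_index"])
        other = (
            intro.classify_panel(shuffled)
            .calls_frame()
            .set_index(["sample", "hap_index"])
        )
        pd.testing.assert_frame_equal(
            base[["origin"]].sort_index(), other[["origin"]].sort_index()
        )

    def test_missing_outgroup_raises(self):
        cfg = CohortConfig(
            n_wild_yak=3, n_domestic_yak=3, n_cattle=3, n_outgroup=1,
            n_snps_per_window=100, n_sv_loci=1, seed=2,
        )
        cohort = simulate_cohort(cfg)
        panel = intro.panels_from_cohort(cohort)[0]
        keep = panel.populations != "outgroup"
        trimmed = intro.HaplotypePanel(
            sv_id=panel.sv_id, positions=panel.positions,
            sequences=panel.sequences[keep],
            samples=[s for s, k in zip(panel.samples, keep) if k],
            hap_index=panel.hap_index[keep],
            populations=panel.populations[keep],
            sv_alleles=panel.sv_alleles[keep],
        )
        with pytest.raises(intro.ClassificationError, match="outgroup"):
            intro.classify_panel(trimmed)
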