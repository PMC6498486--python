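"""The cell-mixture cohort generator: determinism, planted-truth recovery,
marker specificity, count marginals and the closed-form mixture oracle."""

import numpy as np
import pandas as pd
import pytest

import bloodshift as bs
from bloodshift.synthetic import (
    BASELINE_CELL_FRACTIONS,
    CELL_TYPES,
    CohortDesign,
    expected_group_mean,
    generate_signatures,
    timecourse_dataset,
)


class TestGenerateAnnotation:
    def test_deterministic(self):
        a = bs.generate_annotation(100, seed=7)
        b = bs.generate_annotation(100, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = bs.generate_annotation(100, seed=8)
        assert not a.equals(c)

    def test_degenerate_mixture(self):
        ann = bs.generate_annotation(50, biotype_mix={"protein_coding": 1.0}, seed=0)
        assert (ann["biotype"] == "protein_coding").all()

    def test_mixture_proportions_recovered(self):
        """Empirical biotype proportions track the requested mixture."""
        mix = {
            "protein_coding": 0.5,
            "retained_intron": 0.217,
            "processed_transcript": 0.12,
            "other": 0.163,
        }
        ann = bs.generate_annotation(10000, biotype_mix=mix, seed=3)
        props = ann["biotype"].value_counts(normalize=True)
        for biotype, p in mix.items():
            assert abs(props[biotype] - p) < 0.02

    def test_marker_assignment_counts(self):
        config = {"CD4T": 5, "NEUTROPHIL": 3}
        ann = bs.generate_annotation(200, marker_config=config, seed=1)
        counts = ann["marker_of"].value_counts()
        assert counts["CD4T"] == 5 and counts["NEUTROPHIL"] == 3
        assert counts["NONE"] == 192

    def test_invariants(self):
        ann = bs.generate_annotation(500, seed=2)
        assert ann.index.is_unique
        assert (ann["exonic_length"] >= 1).all()
        assert (ann["intronic_length"] >= 0).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="normalisable"):
            bs.generate_annotation(10, biotype_mix={"protein_coding": -1.0})
        with pytest.raises(ValueError, match="marker demand"):
            bs.generate_annotation(5, marker_config={"CD4T": 10})


class TestSignatures:
    def test_marker_specificity_invariant(self):
        """Marker baseline is spec_fold x the max across other cell types."""
        ann = bs.generate_annotation(300, marker_config={ct: 4 for ct in CELL_TYPES}, seed=4)
        sig = generate_signatures(ann, seed=4, spec_fold=10.0)
        assert (sig.to_numpy() >= 0).all()
        for tid, row in ann[ann["marker_of"] != "NONE"].iterrows():
            own = sig.at[tid, row["marker_of"]]
            others = sig.loc[tid].drop(row["marker_of"]).max()
            assert own >= 10.0 * others - 1e-9


def _tiny_inputs(n=40, seed=9, pure_markers=False, **design_kw):
    ann = bs.generate_annotation(n, marker_config={"CD4T": 3, "MONO_CLASSICAL": 3}, seed=seed)
    sig = generate_signatures(ann, seed=seed)
    if pure_markers:
        # zero cross-expression: the marker is expressed only in its own type
        for tid, row in ann[ann["marker_of"] != "NONE"].iterrows():
            own = sig.at[tid, row["marker_of"]]
            sig.loc[tid] = 0.0
            sig.at[tid, row["marker_of"]] = own
    design = CohortDesign(group_sizes={"RAA": 6, "RAC": 6, "C": 6}, seed=seed, **design_kw)
    return ann, sig, design


class TestGenerateCohort:
    def test_deterministic(self):
        ann, sig, design = _tiny_inputs()
        ex1, in1, cells1, _ = bs.generate_cohort(ann, sig, design)
        ex2, in2, cells2, _ = bs.generate_cohort(ann, sig, design)
        pd.testing.assert_frame_equal(ex1.values, ex2.values)
        pd.testing.assert_frame_equal(in1.values, in2.values)
        pd.testing.assert_frame_equal(cells1, cells2)

    def test_null_design_expected_folds_all_one(self):
        ann, sig, design = _tiny_inputs()
        _, _, _, truth = bs.generate_cohort(ann, sig, design)
        np.testing.assert_allclose(truth.expected_folds.to_numpy(), 1.0, rtol=1e-12)

    def test_counts_are_nonnegative_integers_and_split_consistently(self):
        ann, sig, design = _tiny_inputs(premrna_baseline=0.3)
        ex, intr, _, _ = bs.generate_cohort(ann, sig, design)
        for em in (ex, intr):
            arr = em.values.to_numpy()
            assert (arr >= 0).all() and np.allclose(arr, np.round(arr))
        # the realised intronic share across the cohort tracks the planted fraction
        total = ex.values.to_numpy() + intr.values.to_numpy()
        share = intr.values.to_numpy().sum() / total.sum()
        assert abs(share - 0.3) < 0.01

    def test_premrna_zero_means_no_intronic_reads(self):
        """Exonic counts then carry the whole realised total exactly."""
        ann, sig, design = _tiny_inputs(premrna_baseline=0.0)
        ex, intr, _, _ = bs.generate_cohort(ann, sig, design)
        assert intr.values.to_numpy().sum() == 0
        assert ex.values.to_numpy().sum() > 0

    def test_cell_table_parent_child_consistency(self, small_cohort):
        _, _, cells, _ = small_cohort
        num = cells.drop(columns="group")
        assert (num.to_numpy() >= 0).all()
        np.testing.assert_allclose(cells["CD3"], cells["CD4"] + cells["CD8"], rtol=1e-9)
        assert (cells["CD3"] <= cells["lymphocytes"] + 1e-9).all()
        assert (cells["CD4"] <= cells["CD3"] + 1e-9).all()
        assert (cells["mono_classical"] <= cells["monocytes"] + 1e-9).all()
        np.testing.assert_allclose(
            cells["monocytes"],
            cells["mono_classical"] + cells["mono_intermediate"] + cells["mono_nonclassical"],
            rtol=1e-9,
        )

    def test_cd4_depletion_fold_matches_mixture_oracle(self):
        """Closed-form oracle: a pure CD4 marker under a 1/1.5 count shift.

        fold = (p_CD4(RAA)/p_CD4(C)) / (Z_RAA/Z_C) where p are the
        normalised expected proportions and Z the per-group total-RNA
        renormalisers, evaluated here independently of the package.
        """
        ann, sig, design = _tiny_inputs(pure_markers=True)
        design.cellcount_multiplier = {"RAA": {"CD4T": 1 / 1.5}}
        _, _, _, truth = bs.generate_cohort(ann, sig, design)

        def oracle_mean(group):
            mult = {"RAA": {"CD4T": 1 / 1.5}}.get(group, {})
            w = np.array(
                [BASELINE_CELL_FRACTIONS[ct] * mult.get(ct, 1.0) for ct in CELL_TYPES]
            )
            p = w / w.sum()
            raw = sig.to_numpy() @ p
            return design.library_size * raw / raw.sum()

        expected = oracle_mean("RAA") / oracle_mean("C")
        np.testing.assert_allclose(
            truth.expected_folds["RAA_vs_C"].to_numpy(), expected, rtol=1e-12
        )
        cd4_markers = ann.index[ann["marker_of"] == "CD4T"]
        fold = truth.expected_folds.loc[cd4_markers, "RAA_vs_C"]
        # (1/1.5) divided by the proportion- and total-RNA renormalisation,
        # which is mild because CD4 cells are a modest share of the mixture
        assert ((fold > 0.6) & (fold < 0.78)).all()
        assert (fold / fold.iloc[0]).std() < 1e-12  # identical for pure markers

    def test_monocyte_scenario_fold_in_printed_envelope(self):
        """Count x1.3 with regulation x2.5 lands near 3.25 before
        renormalisation, inside the 1.8-4.6 marker-fold envelope."""
        ann, sig, design = _tiny_inputs(n=400, pure_markers=True)
        mono_markers = list(ann.index[ann["marker_of"] == "MONO_CLASSICAL"])
        design.cellcount_multiplier = {"RAA": {"MONO_CLASSICAL": 1.3}}
        design.regulation_multiplier = {
            "RAA": {"MONO_CLASSICAL": {t: 2.5 for t in mono_markers}}
        }
        _, _, _, truth = bs.generate_cohort(ann, sig, design)
        fold = truth.expected_folds.loc[mono_markers, "RAA_vs_C"]
        assert ((fold > 1.8) & (fold < 4.6)).all()
        # independent oracle: full mixture formula evaluated from scratch
        def oracle_mean(group):
            mult = 1.3 if group == "RAA" else 1.0
            reg = 2.5 if group == "RAA" else 1.0
            w = np.array(
                [
                    BASELINE_CELL_FRACTIONS[ct] * (mult if ct == "MONO_CLASSICAL" else 1.0)
                    for ct in CELL_TYPES
                ]
            )
            p = w / w.sum()
            eff = sig.to_numpy().copy()
            k = CELL_TYPES.index("MONO_CLASSICAL")
            rows = [list(ann.index).index(t) for t in mono_markers]
            eff[rows, k] *= reg
            raw = eff @ p
            return design.library_size * raw / raw.sum()

        expected = oracle_mean("RAA") / oracle_mean("C")
        np.testing.assert_allclose(
            truth.expected_folds["RAA_vs_C"].to_numpy(), expected, rtol=1e-12
        )
        # the raw planted product 1.3 * 2.5 = 3.25, shrunk only mildly by
        # the compositional renormalisation
        assert fold.mean() == pytest.approx(3.25, rel=0.1)

    def test_mixture_means_converge_to_truth(self):
        """Empirical per-group means approach the closed-form expectation."""
        ann = bs.generate_annotation(400, marker_config={"CD4T": 5}, seed=21)
        sig = generate_signatures(ann, seed=21)
        design = CohortDesign(
            group_sizes={"RAA": 20, "RAC": 20, "C": 20},
            cellcount_multiplier={"RAA": {"CD4T": 1 / 1.5}},
            dispersion=0.02,
            library_size=1e6,
            seed=21,
        )
        ex, intr, _, truth = bs.generate_cohort(ann, sig, design)
        exonic = ex.values
        rel_errs = []
        for g in ("RAA", "RAC", "C"):
            cols = [s for s in exonic.columns if s.startswith(g)]
            emp = exonic[cols].mean(axis=1)
            exp = truth.expected_group_means[g]
            rel_errs.append(((emp - exp).abs() / exp).to_numpy())
        assert np.median(np.concatenate(rel_errs)) < 0.05

    def test_errors(self):
        ann, sig, design = _tiny_inputs()
        with pytest.raises(KeyError, match="missing transcripts"):
            bs.generate_cohort(ann, sig.iloc[5:], design)
        design.library_size = 0
        with pytest.raises(ValueError, match="library_size"):
            bs.generate_cohort(ann, sig, design)


class TestCohortDesignValidation:
    def test_control_multipliers_must_be_one(self):
        design = CohortDesign(cellcount_multiplier={"C": {"CD4T": 2.0}})
        with pytest.raises(ValueError, match="identically 1"):
            design.validate()

    def test_premrna_range(self):
        with pytest.raises(ValueError, match="premrna"):
            CohortDesign(premrna_baseline=1.0).validate()

    def test_positive_multipliers(self):
        design = CohortDesign(cellcount_multiplier={"RAA": {"CD4T": 0.0}})
        with pytest.raises(ValueError, match="positive"):
            design.validate()


class TestDefaultScenario:
    def test_valid_and_deterministic(self):
        a = bs.default_acute_scenario(1, n_transcripts=300)
        b = bs.default_acute_scenario(1, n_transcripts=300)
        a.design.validate()
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
        assert a.design == b.design

    def test_chronic_group_is_at_control_levels(self):
        sc = bs.default_acute_scenario(1, n_transcripts=300)
        for ct in CELL_TYPES:
            assert sc.design.count_multiplier("RAC", ct) == 1.0
        assert sc.design.regulation_multiplier.get("RAC", {}) == {}
        assert sc.design.premrna_override.get("RAC", {}) == {}

    def test_planted_effects(self):
        sc = bs.default_acute_scenario(2, n_transcripts=300)
        assert sc.design.count_multiplier("RAA", "CD4T") == pytest.approx(1 / 1.5)
        assert sc.design.count_multiplier("RAA", "CD8T") < 1.0
        assert sc.design.count_multiplier("RAA", "MONO_CLASSICAL") == pytest.approx(1.3)
        regs = [
            m
            for per_ct in sc.design.regulation_multiplier["RAA"].values()
            for m in per_ct.values()
        ]
        assert regs and all(m == 2.5 for m in regs)
        fractions = set(sc.design.premrna_override["RAA"].values())
        assert fractions == {0.4}

    def test_lmn_genes_all_mapped(self):
        sc = bs.default_acute_scenario(3, n_transcripts=300)
        assert len(sc.genesets.transcript_map) == 16
        assert set(sc.genesets.transcript_map.values()) <= set(sc.annotation.index)


def test_timecourse_dataset_shape_and_determinism():
    em1, planted = timecourse_dataset(n_null=30, seed=5)
    em2, _ = timecourse_dataset(n_null=30, seed=5)
    pd.testing.assert_frame_equal(em1.values, em2.values)
    assert planted in em1.values.index
    assert em1.samples["months_since_event"].between(3, 15).all()
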