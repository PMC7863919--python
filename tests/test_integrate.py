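"""Target gating, Spearman screening, and sign-concordance attribution."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortimir import (
    IntegrationAnalysis,
    attribute_degs,
    concordance,
    correlation_screen,
    filter_targets,
    spearman,
    split_by_sign,
    targets_per_mirna,
)
from cortimir.fixtures import load_table4_integration, table4_attribution_inputs


def predictions(*rows):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "confidence_class"])


class TestFilterTargets:
    def test_only_top_class_survives_default_gate(self):
        preds = predictions(("m1", "g1", "VeryHigh"), ("m1", "g2", "High"))
        out = filter_targets(preds)
        assert out[["mirna_id", "gene_id"]].values.tolist() == [["m1", "g1"]]

    def test_empty_result_is_not_an_error(self):
        out = filter_targets(predictions(("m1", "g1", "Low")))
        assert out.empty

    def test_lowest_gate_is_identity(self):
        preds = predictions(
            ("m1", "g1", "VeryHigh"), ("m1", "g2", "High"),
            ("m2", "g3", "Medium"), ("m2", "g4", "Low"),
        )
        assert len(filter_targets(preds, min_class="Low")) == 4

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            filter_targets(predictions(("m1", "g1", "Certain")))
        with pytest.raises(ValueError):
            filter_targets(predictions(("m1", "g1", "High")), min_class="Best")

    def test_duplicate_pairs_rejected(self):
        preds = predictions(("m1", "g1", "High"), ("m1", "g1", "Low"))
        with pytest.raises(ValueError):
            filter_targets(preds)


def _spearman_oracle(x, y):
    """Explicit average ranks, then Pearson on the ranks."""
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_pairs(self):
        rho, p, n = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        assert p == pytest.approx(2 / math.factorial(4))
        rho, p, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == -1.0

    def test_hand_ranked_example(self):
        rho, p, n = spearman([1, 2, 3, 4, 5, 6], [1, 3, 2, 4, 6, 5])
        assert rho == pytest.approx(0.8857, abs=5e-5)
        assert n == 6

    def test_pvalue_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p, n = spearman(x, y)
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        if seed % 2:  # force ties half the time
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
        else:
            x, y = rng.normal(size=n), rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, _, _ = spearman(x, y)
        assert rho == pytest.approx(_spearman_oracle(x, y))

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho, p, _ = spearman(x, y)
        rho2, p2, _ = spearman(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho)
        assert p2 == pytest.approx(p)

    def test_missing_values_removed_pairwise(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 6, 8, np.nan, 12]
        rho, p, n = spearman(x, y)
        assert n == 4
        assert rho == 1.0

    def test_constant_vector_flagged_na(self):
        rho, p, n = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestConcordance:
    @pytest.mark.parametrize(
        "rho,gene_fc,mirna_fc,expected",
        [
            (-0.739, 0.55, 2.09, True),   # negative rho, opposite directions
            (0.601, 2.67, 2.11, True),    # positive rho, same direction
            (-0.5, 2.0, 2.0, False),      # negative rho, same direction
            (0.5, 0.5, 2.0, False),       # positive rho, opposite directions
            (-0.659, 1.65, 0.37, True),   # gene up, miRNA down
        ],
    )
    def test_sign_rule(self, rho, gene_fc, mirna_fc, expected):
        assert concordance(rho, gene_fc, mirna_fc) is expected

    def test_symmetric_under_simultaneous_inversion(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            rho = float(rng.uniform(-1, 1)) or 0.5
            gfc = float(np.exp(rng.normal()))
            mfc = float(np.exp(rng.normal()))
            if gfc == 1 or mfc == 1:
                continue
            assert concordance(rho, gfc, mfc) == concordance(-rho, 1 / gfc, mfc)

    def test_unit_fold_change_warns_and_is_false(self):
        with pytest.warns(UserWarning):
            assert concordance(-0.5, 1.0, 2.0) is False

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            concordance(0.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            concordance(-0.5, -2.0, 2.0)


class TestSplitBySign:
    def test_fixture_positive_side_has_four_genes(self):
        records, _, _ = table4_attribution_inputs()
        negative, positive = split_by_sign(records)
        assert positive["gene_id"].nunique() == 4
        assert negative["gene_id"].nunique() == 21

    def test_all_negative_input(self):
        records = pd.DataFrame({"mirna_id": ["m"], "gene_id": ["g"], "rho": [-0.5]})
        negative, positive = split_by_sign(records)
        assert len(negative) == 1 and positive.empty

    def test_zero_rho_excluded_with_warning(self):
        records = pd.DataFrame(
            {"mirna_id": ["m", "m2"], "gene_id": ["g", "g2"], "rho": [0.0, 0.4]}
        )
        with pytest.warns(UserWarning):
            negative, positive = split_by_sign(records)
        assert len(negative) == 0 and len(positive) == 1


class TestAttributeDegs:
    def test_fixture_aggregations(self):
        records, deg, dem = table4_attribution_inputs()
        out = attribute_degs(records, deg, dem)
        assert out["gene_id"].nunique() == 25
        assert out["mirna_id"].nunique() == 12
        assert out["concordant"].all()

    def test_fixture_rows_reproduced_without_extras(self):
        records, deg, dem = table4_attribution_inputs()
        out = attribute_degs(records, deg, dem)
        printed = load_table4_integration()
        assert set(zip(out.gene_id, out.mirna_id)) == set(
            zip(printed.gene_id, printed.mirna_id)
        )
        assert len(out) == len(printed)

    def test_empty_deg_table_gives_empty_output(self):
        records, deg, dem = table4_attribution_inputs()
        no_degs = deg.assign(is_deg=False)
        assert attribute_degs(records, no_degs, dem).empty

    def test_orphan_keys_rejected(self):
        records, deg, dem = table4_attribution_inputs()
        with pytest.raises(KeyError, match="PGGT1B"):
            attribute_degs(records, deg.drop(index="PGGT1B"), dem)


class TestTargetsPerMirna:
    def test_direct_counts_and_median(self):
        records = pd.DataFrame(
            {"mirna_id": ["m1", "m1", "m2"], "gene_id": ["g1", "g2", "g3"],
             "rho": [-0.6, -0.7, 0.6]}
        )
        counts = targets_per_mirna(records)
        assert dict(zip(counts.mirna_id, counts.n_targets)) == {"m1": 2, "m2": 1}
        assert counts.attrs["median"] == 1.5

    def test_single_record(self):
        records = pd.DataFrame({"mirna_id": ["m"], "gene_id": ["g"], "rho": [0.7]})
        assert targets_per_mirna(records).attrs["median"] == 1

    def test_fixture_mir_382_has_ten_targets(self):
        records, _, _ = table4_attribution_inputs()
        counts = targets_per_mirna(records).set_index("mirna_id")
        assert counts.loc["hsa-miR-382-5p", "n_targets"] == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            targets_per_mirna(pd.DataFrame(columns=["mirna_id", "gene_id"]))


class TestCorrelationScreen:
    def test_planted_negative_coupling_retained(self, default_cohort, fitted_de):
        mirna_res, mrna_res = fitted_de
        gated = filter_targets(default_cohort.target_map)
        records = correlation_screen(
            mirna_res.dem_ids, gated, mirna_res.normalized, mrna_res.normalized
        )
        truth = default_cohort.truth_couplings
        neg = truth.loc[truth.sign == "-"]
        merged = records.merge(neg, on=["mirna_id", "gene_id"])
        assert len(merged) > 0
        assert (merged["rho"] < 0).all()

    def test_empty_dem_list_gives_empty_output(self, default_cohort, fitted_de):
        mirna_res, mrna_res = fitted_de
        records = correlation_screen(
            [], default_cohort.target_map, mirna_res.normalized, mrna_res.normalized
        )
        assert records.empty

    def test_no_matched_samples_is_an_error(self, fitted_de):
        mirna_res, mrna_res = fitted_de
        renamed = mrna_res.normalized.rename(columns=lambda s: s + "_other")
        with pytest.raises(ValueError, match="matched samples"):
            correlation_screen(
                mirna_res.dem_ids, pd.DataFrame(columns=["mirna_id", "gene_id"]),
                mirna_res.normalized, renamed,
            )


class TestIntegrationModel:
    def test_end_to_end_precision_against_truth(self, default_cohort, fitted_de):
        mirna_res, mrna_res = fitted_de
        results = IntegrationAnalysis(
            mirna_res, mrna_res, default_cohort.target_map
        ).fit()
        assert len(results.attributed) > 0
        truth = set(
            map(tuple, default_cohort.truth_couplings[["mirna_id", "gene_id"]].values)
        )
        reported = set(
            map(tuple, results.attributed[["mirna_id", "gene_id"]].values)
        )
        assert len(reported & truth) / len(reported) >= 0.7

    def test_summary_reports_sign_split(self, default_cohort, fitted_de):
        mirna_res, mrna_res = fitted_de
        results = IntegrationAnalysis(mirna_res, mrna_res, default_cohort.target_map).fit()
        assert f"{len(results.negative)} negative" in results.summary()
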