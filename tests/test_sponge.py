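import math

import numpy as np
import pandas as pd
import pytest

from spongescan.errors import EmptyInputError
from spongescan.sponge import (
    _es_batch,
    assemble_score_matrix,
    compute_enrich_sg,
    compute_sg,
    compute_sponge_scores,
)

from oracles import gsea_es_reference, gsea_exact_pvalue, topsis_reference


def mrna_pair_table(rows):
    """rows of (mirna, mrna, s_affinity, s_nbmre)"""
    return pd.DataFrame(
        {
            "mirna_id": [r[0] for r in rows],
            "target_id": [r[1] for r in rows],
            "target_type": "mRNA",
            "raw_score_best": -0.3,
            "n_sites": 1,
            "s_affinity": [r[2] for r in rows],
            "s_nbmre": [r[3] for r in rows],
        }
    )


def eligible_frame(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "circ_id", "mrna_ids"])


class TestComputeSg:
    def test_single_pair_half(self):
        pairs = mrna_pair_table([("m1", "g1", 0.5, 2)])
        fc = pd.Series({"g1": 1.0})
        mirexpr = pd.Series({"m1": 5.0})
        targetexpr = pd.Series({"g1": 6.0})
        eligible = eligible_frame([("m1", "c1", ("g1",))])
        out = compute_sg(pairs, fc, mirexpr, targetexpr, eligible)
        assert out.iloc[0]["sg"] == pytest.approx(0.5)

    def test_dominance(self):
        pairs = mrna_pair_table([("m1", "g1", 1.0, 5), ("m2", "g2", 0.2, 1)])
        fc = pd.Series({"g1": 3.0, "g2": 0.5})
        mirexpr = pd.Series({"m1": 9.0, "m2": 2.0})
        targetexpr = pd.Series({"g1": 10.0, "g2": 4.0})
        eligible = eligible_frame(
            [("m1", "c1", ("g1",)), ("m2", "c1", ("g2",))]
        )
        out = compute_sg(pairs, fc, mirexpr, targetexpr, eligible).set_index("mirna_id")
        assert out.loc["m1", "sg"] == pytest.approx(1.0)
        assert out.loc["m2", "sg"] == pytest.approx(0.0)

    def test_no_eligible_pair_raises(self):
        pairs = mrna_pair_table([("m1", "g1", 0.5, 2)])
        with pytest.raises(EmptyInputError):
            compute_sg(
                pairs,
                pd.Series(dtype=float),
                pd.Series(dtype=float),
                pd.Series(dtype=float),
                eligible_frame([]),
            )

    def test_matches_topsis_oracle(self):
        rng = np.random.default_rng(4)
        mirnas = [f"m{i}" for i in range(5)]
        rows = [
            (m, f"g{j}", float(rng.uniform(0, 1)), float(rng.integers(1, 6)))
            for m in mirnas
            for j in range(2)
        ]
        pairs = mrna_pair_table(rows)
        genes = sorted({r[1] for r in rows})
        fc = pd.Series({g: float(rng.normal(0, 2)) for g in genes})
        mirexpr = pd.Series({m: float(rng.uniform(2, 10)) for m in mirnas})
        targetexpr = pd.Series({g: float(rng.uniform(2, 10)) for g in genes})
        eligible = eligible_frame(
            [(m, "c1", tuple(sorted({r[1] for r in rows if r[0] == m}))) for m in mirnas]
        )
        out = compute_sg(pairs, fc, mirexpr, targetexpr, eligible)
        ordered = pairs.sort_values(["mirna_id", "target_id"]).reset_index(drop=True)
        matrix = [
            [
                row["s_affinity"],
                row["s_nbmre"],
                abs(fc[row["target_id"]]),
                mirexpr[row["mirna_id"]],
                targetexpr[row["target_id"]],
            ]
            for _, row in ordered.iterrows()
        ]
        want = topsis_reference(matrix, ["benefit"] * 5)
        np.testing.assert_allclose(out["sg"].to_numpy(), want, atol=1e-12)


class TestEnrichmentScore:
    def test_es_matches_reference_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            scores = np.sort(rng.uniform(0, 1, n))[::-1]
            k = int(rng.integers(1, n))
            pos = np.sort(rng.choice(n, size=k, replace=False))
            got = float(_es_batch(pos[None, :], scores, n)[0])
            want = gsea_es_reference(list(pos), list(scores))
            assert got == pytest.approx(want, abs=1e-12)

    def test_full_set_es_one(self):
        scores = np.array([0.9, 0.5, 0.2])
        assert _es_batch(np.arange(3)[None, :], scores, 3)[0] == pytest.approx(1.0)


def sg_frame(entries):
    """entries of (mirna, mrna, sg)"""
    return pd.DataFrame(
        {
            "mirna_id": [e[0] for e in entries],
            "mrna_id": [e[1] for e in entries],
            "sg": [e[2] for e in entries],
        }
    )


class TestComputeEnrichSg:
    def test_exact_top_of_three(self):
        sg = sg_frame([("m1", "g1", 0.9), ("m2", "g2", 0.5), ("m2", "g3", 0.1)])
        out = compute_enrich_sg(sg, nperm=100, seed=0).set_index("mirna_id")
        assert out.loc["m1", "pvalue"] == pytest.approx(1 / 3)

    def test_owner_of_everything(self):
        sg = sg_frame([("m1", "g1", 0.9), ("m1", "g2", 0.5), ("m1", "g3", 0.1)])
        out = compute_enrich_sg(sg, nperm=100, seed=0)
        assert out.iloc[0]["es"] == pytest.approx(1.0)
        assert out.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        entries = []
        for i, m in enumerate(["m1", "m1", "m2", "m2", "m2", "m3", "m3"]):
            entries.append((m, f"g{i}", float(rng.uniform(0, 1))))
        sg = sg_frame(entries)
        out = compute_enrich_sg(sg, nperm=100, seed=0).set_index("mirna_id")
        ranked = sg.sort_values(
            ["sg", "mirna_id", "mrna_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        scores = ranked["sg"].tolist()
        for mirna in ["m1", "m2", "m3"]:
            pos = ranked.index[ranked["mirna_id"] == mirna].tolist()
            assert out.loc[mirna, "es"] == pytest.approx(
                gsea_es_reference(pos, scores), abs=1e-12
            )
            assert out.loc[mirna, "pvalue"] == pytest.approx(
                gsea_exact_pvalue(pos, scores), abs=1e-12
            )

    def test_sampled_agrees_with_exact_within_mc_error(self):
        rng = np.random.default_rng(23)
        entries = []
        for i, m in enumerate(["m1", "m1", "m2", "m2", "m2", "m3", "m3"]):
            entries.append((m, f"g{i}", float(rng.uniform(0, 1))))
        sg = sg_frame(entries)
        nperm = 10_000
        exact = compute_enrich_sg(sg, nperm=nperm, seed=1).set_index("mirna_id")
        sampled = compute_enrich_sg(
            sg, nperm=nperm, seed=1, exhaustive_limit=0
        ).set_index("mirna_id")
        for mirna in ["m1", "m2", "m3"]:
            p = exact.loc[mirna, "pvalue"]
            se = math.sqrt(p * (1 - p) / nperm)
            assert abs(sampled.loc[mirna, "pvalue"] - p) <= 3 * se + 2 / nperm

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        entries = [
            (f"m{i % 4}", f"g{i}", float(rng.uniform(0, 1))) for i in range(30)
        ]
        sg = sg_frame(entries)
        a = compute_enrich_sg(sg, nperm=500, seed=42, exhaustive_limit=0)
        b = compute_enrich_sg(sg, nperm=500, seed=42, exhaustive_limit=0)
        pd.testing.assert_frame_equal(a, b)


def circ_pair_table(rows):
    """rows of (mirna, circ, s_affinity, s_nbmre, s_enrichmre)"""
    return pd.DataFrame(
        {
            "mirna_id": [r[0] for r in rows],
            "target_id": [r[1] for r in rows],
            "target_type": "circRNA",
            "raw_score_best": -0.5,
            "n_sites": 2,
            "s_affinity": [r[2] for r in rows],
            "s_nbmre": [r[3] for r in rows],
            "s_enrichmre": [r[4] for r in rows],
        }
    )


def make_ss_inputs(rng, n_mirna=4, n_circ=5):
    mirnas = [f"hsa-miR-{i}-5p" for i in range(n_mirna)]
    circs = [f"hsa_circ_{i:07d}" for i in range(n_circ)]
    genes = [f"G{i}" for i in range(6)]
    circ_rows = [
        (m, c, float(rng.uniform(0, 1)), float(rng.uniform(0, 0.05)), float(rng.uniform(1e-6, 0.05)))
        for m in mirnas
        for c in circs
    ]
    fc_circ = pd.Series({c: float(rng.normal(0, 2)) or 0.5 for c in circs})
    mirexpr = pd.Series({m: float(rng.uniform(2, 10)) for m in mirnas})
    targetexpr = pd.Series({c: float(rng.uniform(2, 12)) for c in circs})
    enrich = pd.DataFrame(
        {
            "mirna_id": mirnas,
            "es": 0.5,
            "pvalue": rng.uniform(0.001, 0.5, n_mirna),
        }
    )
    enrich["s_enrichsg"] = enrich["pvalue"]
    sg = sg_frame([(m, g, float(rng.uniform(0, 1))) for m in mirnas for g in genes])
    eligible = eligible_frame(
        [(m, c, tuple(genes[:3])) for m in mirnas for c in circs]
    )
    return circ_pair_table(circ_rows), fc_circ, mirexpr, targetexpr, enrich, sg, eligible


class TestComputeSpongeScores:
    def test_single_pair_half(self):
        rng = np.random.default_rng(0)
        circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible = make_ss_inputs(
            rng, n_mirna=1, n_circ=1
        )
        out = compute_sponge_scores(
            circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible
        )
        assert out.iloc[0]["ss"] == pytest.approx(0.5)

    def test_dominance(self):
        circ_pairs = circ_pair_table(
            [
                ("hsa-miR-1-5p", "hsa_circ_0000001", 1.0, 0.05, 1e-6),
                ("hsa-miR-2-5p", "hsa_circ_0000002", 0.2, 0.001, 0.04),
            ]
        )
        fc = pd.Series({"hsa_circ_0000001": 4.0, "hsa_circ_0000002": 0.5})
        mirexpr = pd.Series({"hsa-miR-1-5p": 10.0, "hsa-miR-2-5p": 2.0})
        targetexpr = pd.Series({"hsa_circ_0000001": 12.0, "hsa_circ_0000002": 3.0})
        enrich = pd.DataFrame(
            {
                "mirna_id": ["hsa-miR-1-5p", "hsa-miR-2-5p"],
                "es": [0.9, 0.1],
                "pvalue": [0.001, 0.5],
                "s_enrichsg": [0.001, 0.5],
            }
        )
        sg = sg_frame(
            [("hsa-miR-1-5p", "G0", 0.9), ("hsa-miR-2-5p", "G1", 0.2)]
        )
        eligible = eligible_frame(
            [
                ("hsa-miR-1-5p", "hsa_circ_0000001", ("G0",)),
                ("hsa-miR-2-5p", "hsa_circ_0000002", ("G1",)),
            ]
        )
        out = compute_sponge_scores(
            circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible
        ).set_index("mirna_id")
        assert out.loc["hsa-miR-1-5p", "ss"] == pytest.approx(1.0)
        assert out.loc["hsa-miR-2-5p", "ss"] == pytest.approx(0.0)

    def test_matches_seven_criterion_oracle(self):
        rng = np.random.default_rng(77)
        circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible = make_ss_inputs(rng)
        out = compute_sponge_scores(
            circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible
        )
        enrich_by = enrich.set_index("mirna_id")["s_enrichsg"]
        matrix = [
            [
                row["s_affinity"],
                row["s_nbmre"],
                abs(fc[row["circ_id"]]),
                mirexpr[row["mirna_id"]],
                targetexpr[row["circ_id"]],
                enrich_by[row["mirna_id"]],
                row["s_enrichmre"],
            ]
            for _, row in out.iterrows()
        ]
        want = topsis_reference(matrix, ["benefit"] * 5 + ["cost"] * 2)
        np.testing.assert_allclose(out["ss"].to_numpy(), want, atol=1e-12)

    def test_condition_assignment(self):
        rng = np.random.default_rng(3)
        circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible = make_ss_inputs(rng)
        out = compute_sponge_scores(
            circ_pairs, fc, mirexpr, targetexpr, enrich, sg, eligible
        )
        for _, row in out.iterrows():
            expected = "condition_2" if fc[row["circ_id"]] > 0 else "condition_1"
            assert row["condition"] == expected


class TestAssembleScoreMatrix:
    def base_rows(self, ss_values, conditions=None):
        n = len(ss_values)
        conditions = conditions or ["condition_2"] * n
        return pd.DataFrame(
            {
                "mirna_id": [f"hsa-miR-{i}-5p" for i in range(n)],
                "circ_id": ["hsa_circ_0000001"] * n,
                "s_affinity": 0.5,
                "s_nbmre": 0.01,
                "s_enrichmre": 0.01,
                "s_fc_circ": [2.0 if c == "condition_2" else -2.0 for c in conditions],
                "s_mirexpr": 5.0,
                "s_targetexpr_circ": 8.0,
                "s_enrichsg": 0.02,
                "n_mrna_targets": 2,
                "mean_sg_of_targets": 0.5,
                "mrna_target_list": "A;B",
                "ss": ss_values,
                "condition": conditions,
            }
        )

    def test_tie_broken_lexicographically(self):
        out = assemble_score_matrix(self.base_rows([0.5, 0.9, 0.5]))
        assert out["rank_global"].tolist() == [1, 2, 3]
        assert out.iloc[0]["mirna_id"] == "hsa-miR-1-5p"  # ss = 0.9
        # tied 0.5s: miR-0 sorts before miR-2
        assert out.iloc[1]["mirna_id"] == "hsa-miR-0-5p"
        assert out.iloc[2]["mirna_id"] == "hsa-miR-2-5p"

    def test_single_condition_ranks_equal(self):
        out = assemble_score_matrix(self.base_rows([0.9, 0.5, 0.2]))
        assert out["rank_in_condition"].tolist() == out["rank_global"].tolist()

    def test_condition_partition(self):
        conditions = ["condition_1"] * 2 + ["condition_2"] * 3
        out = assemble_score_matrix(
            self.base_rows([0.1, 0.7, 0.9, 0.5, 0.3], conditions)
        )
        counts = out["condition"].value_counts()
        assert counts["condition_1"] == 2 and counts["condition_2"] == 3
        for cond, size in (("condition_1", 2), ("condition_2", 3)):
            sub = out[out["condition"] == cond]
            assert sorted(sub["rank_in_condition"]) == list(range(1, size + 1))
            # within-condition order follows the global order
            assert sub.sort_values("rank_global")["rank_in_condition"].is_monotonic_increasing
        assert sorted(out["rank_global"]) == list(range(1, 6))
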