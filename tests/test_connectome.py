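import numpy as np
import pytest

from petconn.cloud import LabeledPointCloud
from petconn.connectome.build import (
    build_connectome,
    load_connectome,
    mi_effect_map,
    node_variability,
    reduce_to_roi,
    save_connectome,
    with_alpha,
)
from petconn.phantom import EffectSpec, OrganSpec, generate_subject
from petconn.schema import ROISchema

from conftest import make_roi_connectome


@pytest.fixture()
def two_organ_cloud():
    rng = np.random.default_rng(0)
    n = 200
    values = np.exp(0.4 * rng.standard_normal(n))
    pos_a = rng.uniform(0, 50, (n, 3))
    pos_b = rng.uniform(60, 110, (n, 3))
    return LabeledPointCloud(
        np.vstack([pos_a, pos_b]),
        np.concatenate([values, values]),  # identical SUV samples
        np.array(["liver"] * n + ["spleen"] * n, dtype=object),
        "twin",
    )


def test_identical_organs_give_unit_similarity(two_organ_cloud, schema):
    conn = build_connectome(two_organ_cloud, schema, alpha=1.0, target=500, seed=0)
    i, j = conn.roi_names.index("liver"), conn.roi_names.index("spleen")
    assert conn.D[i, j] == pytest.approx(0.0, abs=1e-12)
    assert conn.C[i, j] == pytest.approx(1.0)


def test_internal_consistency(reference_cohort, schema):
    cohort, _, _ = reference_cohort
    conn = build_connectome(cohort[0][0], schema, alpha=1.0, seed=3)
    mi_eff = np.minimum(conn.MI, 1 - 1e-6)
    expect = np.exp(-conn.D * (1 - conn.alpha * mi_eff))
    off = ~np.eye(len(conn.roi_names), dtype=bool)
    assert np.allclose(conn.C[off], expect[off], atol=1e-12)


def test_alpha_validation(two_organ_cloud, schema):
    with pytest.raises(ValueError, match="alpha"):
        build_connectome(two_organ_cloud, schema, alpha=1.0, allow_alpha_one=False)
    with pytest.raises(ValueError, match="alpha"):
        build_connectome(two_organ_cloud, schema, alpha=1.5)
    build_connectome(two_organ_cloud, schema, alpha=1.0, target=100, seed=0)  # default guard


def test_pipeline_determinism(schema):
    cloud = generate_subject(
        [
            OrganSpec("liver", (0, 0, 0), (40, 40, 40), suv_params={"mu": 0.5, "sigma": 0.3}),
            OrganSpec("spleen", (60, 0, 0), (40, 40, 40), suv_params={"mu": 0.2, "sigma": 0.3}),
            OrganSpec("brain", (0, 60, 0), (40, 40, 40), suv_params={"mu": 1.5, "sigma": 0.3}),
        ],
        0.0,
        seed=1,
    )
    a = build_connectome(cloud, schema, alpha=1.0, target=200, seed=9)
    b = build_connectome(cloud, schema, alpha=1.0, target=200, seed=9)
    assert np.array_equal(a.C, b.C)
    assert np.array_equal(a.D, b.D)
    assert np.array_equal(a.MI, b.MI)


def test_alpha_zero_ignores_pairing(schema):
    rng = np.random.default_rng(5)
    n = 300
    specs_vals = {
        "liver": np.exp(0.5 + 0.3 * rng.standard_normal(n)),
        "spleen": np.exp(0.2 + 0.3 * rng.standard_normal(n)),
    }

    def make(shuffle):
        pos, suv, lab = [], [], []
        for off, (name, vals) in enumerate(specs_vals.items()):
            p = rng.uniform(0, 50, (n, 3)) + 100 * off
            if shuffle and name == "spleen":
                p = p[np.random.default_rng(0).permutation(n)]
            pos.append(p)
            suv.append(vals)
            lab.extend([name] * n)
        return LabeledPointCloud(np.vstack(pos), np.concatenate(suv), np.array(lab, dtype=object))

    a = build_connectome(make(False), schema, alpha=0.0, target=n, seed=0)
    b = build_connectome(make(True), schema, alpha=0.0, target=n, seed=0)
    assert np.allclose(a.C, b.C)  # marginals unchanged -> C unchanged at alpha=0


def test_less_than_two_organs_error(schema):
    rng = np.random.default_rng(0)
    cloud = LabeledPointCloud(
        rng.uniform(0, 10, (60, 3)), np.ones(60), np.full(60, "liver", dtype=object)
    )
    with pytest.raises(ValueError, match="2"):
        build_connectome(cloud, schema)


def test_unmapped_label_error(schema):
    rng = np.random.default_rng(0)
    cloud = LabeledPointCloud(
        rng.uniform(0, 10, (60, 3)), np.ones(60), np.full(60, "mystery_organ", dtype=object)
    )
    with pytest.raises(KeyError, match="mystery_organ"):
        build_connectome(cloud, schema)


class TestReduceToROI:
    def make_organ_conn(self, names, c):
        n = len(names)
        c = np.asarray(c, float)
        d = -np.log(np.clip(c, 1e-12, None))
        np.fill_diagonal(d, 0.0)
        from petconn.connectome.build import Connectome

        return Connectome(tuple(names), d, np.eye(n), 0.0, c, level="organ")

    def test_mean_reduction_example(self):
        schema = ROISchema(
            roi_names=("A", "B"), organ_to_roi={"a1": "A", "a2": "A", "b1": "B"}
        )
        c = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        conn = self.make_organ_conn(["a1", "a2", "b1"], c)
        reduced = reduce_to_roi(conn, schema)
        i, j = reduced.roi_names.index("A"), reduced.roi_names.index("B")
        assert reduced.C[i, j] == pytest.approx(0.3)  # mean(0.2, 0.4)
        assert reduced.C[i, i] == 1.0

    def test_single_organ_rois_unchanged(self):
        schema = ROISchema(roi_names=("Liver", "Spleen"), organ_to_roi={"liver": "Liver", "spleen": "Spleen"})
        c = np.array([[1.0, 0.37], [0.37, 1.0]])
        reduced = reduce_to_roi(self.make_organ_conn(["liver", "spleen"], c), schema)
        assert reduced.C[0, 1] == pytest.approx(0.37)

    def test_permutation_invariance(self):
        schema = ROISchema(
            roi_names=("A", "B"), organ_to_roi={"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        rng = np.random.default_rng(0)
        m = rng.uniform(0.1, 0.9, (4, 4))
        c = (m + m.T) / 2
        np.fill_diagonal(c, 1.0)
        names = ["a1", "a2", "b1", "b2"]
        base = reduce_to_roi(self.make_organ_conn(names, c), schema)
        perm = [1, 0, 3, 2]
        permuted = reduce_to_roi(
            self.make_organ_conn([names[p] for p in perm], c[np.ix_(perm, perm)]), schema
        )
        assert np.allclose(base.C, permuted.C)

    def test_empty_roi_warns_and_drops(self):
        schema = ROISchema(roi_names=("A", "B", "C"), organ_to_roi={"a1": "A", "b1": "B"})
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.warns(UserWarning, match="C"):
            reduced = reduce_to_roi(self.make_organ_conn(["a1", "b1"], c), schema)
        assert reduced.roi_names == ("A", "B")


class TestNodeVariability:
    def test_identical_cohort_zero(self):
        conn = make_roi_connectome([[1, 0.5], [0.5, 1]], ["A", "B"])
        out = node_variability([conn, conn, conn])
        assert np.allclose(out.to_numpy(), 0.0)

    def test_hand_computed_three_nodes(self):
        def mat(ab, ac, bc):
            return [[1, ab, ac], [ab, 1, bc], [ac, bc, 1]]

        conns = [
            make_roi_connectome(mat(0.2, 0.4, 0.6), ["A", "B", "C"]),
            make_roi_connectome(mat(0.4, 0.8, 0.6), ["A", "B", "C"]),
        ]
        out = node_variability(conns)
        sd_ab = np.std([0.2, 0.4], ddof=1)
        sd_ac = np.std([0.4, 0.8], ddof=1)
        sd_bc = 0.0
        assert out["A"] == pytest.approx(sd_ab + sd_ac)
        assert out["B"] == pytest.approx(sd_ab + sd_bc)
        assert out["C"] == pytest.approx(sd_ac + sd_bc)

    def test_jittered_roi_ranks_first(self):
        rng = np.random.default_rng(0)
        conns = []
        for _ in range(20):
            c = np.full((4, 4), 0.5)
            np.fill_diagonal(c, 1.0)
            c[0, 1] = c[1, 0] = 0.5 + 0.3 * rng.standard_normal()
            c[0, 2] = c[2, 0] = 0.5 + 0.3 * rng.standard_normal()
            conns.append(make_roi_connectome(np.clip(c, 0.01, 1), ["A", "B", "C", "D"]))
        # force exact diagonal after clipping
        out = node_variability(conns)
        assert out.idxmax() == "A"

    def test_mismatched_roi_sets_error(self):
        a = make_roi_connectome([[1, 0.5], [0.5, 1]], ["A", "B"])
        b = make_roi_connectome([[1, 0.5], [0.5, 1]], ["A", "C"])
        with pytest.raises(ValueError, match="mismatch"):
            node_variability([a, b])


@pytest.mark.filterwarnings("ignore:ROIs with no organs")
class TestMIEffectMap:
    def _organ_conns(self, schema, coupled, n_subjects=3):
        specs = [
            OrganSpec("liver", (0, 0, 0), (40, 40, 40), suv_params={"mu": 0.5, "sigma": 0.3}),
            OrganSpec("spleen", (60, 0, 0), (40, 40, 40), suv_params={"mu": 0.4, "sigma": 0.3}),
            OrganSpec("brain", (0, 60, 0), (40, 40, 40), suv_params={"mu": 1.5, "sigma": 0.3}),
        ]
        effect = (
            EffectSpec(coupling=(("liver", "spleen"),), coupling_strength=0.8)
            if coupled
            else None
        )
        out = []
        for s in range(n_subjects):
            cloud = generate_subject(specs, 0.05, seed=50 + s, effect=effect)
            out.append(build_connectome(cloud, schema, alpha=1.0, target=1500, seed=s))
        return out

    def test_identical_groups_zero(self, schema):
        conns = self._organ_conns(schema, coupled=False)
        out = mi_effect_map(conns, conns, schema)
        assert np.allclose(out, 0.0)

    def test_coupled_pair_attains_max(self, schema):
        patients = self._organ_conns(schema, coupled=True)
        controls = self._organ_conns(schema, coupled=False)
        out = mi_effect_map(patients, controls, schema)
        assert np.all(out >= 0)
        assert np.allclose(out, out.T)
        rois = reduce_to_roi(patients[0], schema).roi_names
        i, j = rois.index("Liver"), rois.index("Spleen")
        iu, ju = np.triu_indices(len(rois), k=1)
        assert out[i, j] == pytest.approx(out[iu, ju].max())

    def test_scaling(self, schema):
        patients = self._organ_conns(schema, coupled=True, n_subjects=2)
        controls = self._organ_conns(schema, coupled=False, n_subjects=2)
        a = mi_effect_map(patients, controls, schema, scale=1.0)
        b = mi_effect_map(patients, controls, schema, scale=1e3)
        assert np.allclose(b, 1e3 * a)


def test_with_alpha_recomputes(reference_cohort, schema):
    cohort, _, _ = reference_cohort
    conn = build_connectome(cohort[0][0], schema, alpha=1.0, seed=0)
    at0 = with_alpha(conn, 0.0)
    assert np.allclose(at0.C, np.exp(-conn.D))


def test_connectome_roundtrip(tmp_path, reference_cohort):
    _, conns, _ = reference_cohort
    meta = save_connectome(conns[0], tmp_path)
    back = load_connectome(meta)
    assert back.roi_names == conns[0].roi_names
    assert np.allclose(back.C, conns[0].C)
    assert np.allclose(back.D, conns[0].D)
    assert back.alpha == conns[0].alpha
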