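import numpy as np
import pandas as pd
import pytest

from erndim import phenotype, synth_cohort as sc


def _responses(n=20, seed=0):
    return sc.simulate_items(sc.LatentModel(seed=seed), n)


def test_scale_totals_floor_without_reverse_items():
    manifest = sc.default_manifest()
    manifest["reverse_scored"] = False
    resp = pd.DataFrame(
        [manifest["min_response"].to_list()], columns=manifest["item_id"], index=["s001"]
    )
    totals = phenotype.score_scales(resp, manifest)
    for scale, grp in manifest.groupby("scale"):
        assert totals.loc["s001", scale] == grp["min_response"].sum()
    assert totals.loc["s001", "STAI"] == 20  # STAI coded 1–4
    assert totals.loc["s001", "OCIR"] == 0


def test_reverse_items_flip_within_coding_range():
    manifest = sc.default_manifest()
    resp = pd.DataFrame(
        [manifest["min_response"].to_list()], columns=manifest["item_id"], index=["s001"]
    )
    totals = phenotype.score_scales(resp, manifest)
    rev = manifest[(manifest["scale"] == "STAI") & manifest["reverse_scored"]]
    # minimum raw answers on reverse-keyed items score at the item maximum
    assert totals.loc["s001", "STAI"] == 20 + len(rev) * 3


@pytest.mark.parametrize("total,flag", [(20, False), (21, True), (25, True)])
def test_ocir_clinical_cutoff_inclusive(total, flag):
    manifest = sc.default_manifest()
    resp = pd.DataFrame(
        [manifest["min_response"].to_list()], columns=manifest["item_id"], index=["s001"]
    )
    ocir = manifest.loc[manifest["scale"] == "OCIR", "item_id"]
    left = total
    for item in ocir:
        v = min(left, 4)
        resp[item] = v
        left -= v
    totals = phenotype.score_scales(resp, manifest)
    assert totals.loc["s001", "OCIR"] == total
    assert bool(totals.loc["s001", "ocir_ge_21"]) is flag


@pytest.mark.parametrize("total,flag", [(41, False), (42, True)])
def test_stai_clinical_cutoff_strict(total, flag):
    manifest = sc.default_manifest()
    manifest.loc[manifest["scale"] == "STAI", "reverse_scored"] = False
    resp = pd.DataFrame(
        [manifest["min_response"].to_list()], columns=manifest["item_id"], index=["s001"]
    )
    stai = list(manifest.loc[manifest["scale"] == "STAI", "item_id"])
    left = total - 20  # items floor at 1
    for item in stai:
        v = min(left, 3)
        resp[item] = 1 + v
        left -= v
    totals = phenotype.score_scales(resp, manifest)
    assert totals.loc["s001", "STAI"] == total
    assert bool(totals.loc["s001", "stai_gt_41"]) is flag


def test_missing_item_error_names_item():
    out = _responses(5)
    resp = out["responses"].drop(columns=["OCIR_03"])
    with pytest.raises(KeyError, match="OCIR_03"):
        phenotype.score_scales(resp, out["manifest"])


def test_projection_indicator_weight_returns_item():
    out = _responses(10)
    w = phenotype.synthetic_default_weights() * 0.0
    w.iloc[0, 0] = 1.0  # AD = first item's response
    dims = phenotype.project_dimensions(out["responses"], w, zscore=False)
    assert np.array_equal(
        dims["AD"].to_numpy(), out["responses"].iloc[:, 0].to_numpy(dtype=float)
    )
    assert (dims["CIT"] == 0).all() and (dims["SW"] == 0).all()


def test_projection_zero_responses():
    manifest = sc.default_manifest()
    resp = pd.DataFrame(
        np.zeros((3, 209)), columns=manifest["item_id"], index=["a", "b", "c"]
    )
    dims = phenotype.project_dimensions(resp, zscore=False)
    assert (dims[["AD", "CIT", "SW"]] == 0).all().all()


def test_projection_linearity():
    out = _responses(8, seed=1)
    resp = out["responses"].drop(columns="catch_response").astype(float)
    w = phenotype.synthetic_default_weights()
    p = lambda x: phenotype.project_dimensions(x, w, zscore=False)[["AD", "CIT", "SW"]]
    combo = p(2.0 * resp + 3.0 * resp)
    expected = 2.0 * p(resp) + 3.0 * p(resp)
    assert np.allclose(combo.to_numpy(), expected.to_numpy(), atol=1e-9)


def test_projection_row_count_mismatch():
    out = _responses(5)
    with pytest.raises(ValueError):
        phenotype.project_dimensions(
            out["responses"], phenotype.synthetic_default_weights().iloc[:100]
        )


def test_projected_scores_recover_true_factors():
    out = _responses(2000, seed=2)
    dims = phenotype.project_dimensions(out["responses"])
    for dim in ("AD", "CIT", "SW"):
        r = np.corrcoef(dims[dim], out["truth"][dim])[0, 1]
        assert r > 0.9


def test_zscore_columns_standardised():
    out = _responses(300, seed=3)
    dims = phenotype.project_dimensions(out["responses"])
    for dim in ("AD", "CIT", "SW"):
        z = dims[f"{dim}_z"].to_numpy()
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_inter_dimension_correlations_in_moderate_band():
    """Projected raw-score correlations stay near the generator's
    0.33–0.39 factor-correlation targets (± 0.1)."""
    out = _responses(2000, seed=4)
    dims = phenotype.project_dimensions(out["responses"])
    target = sc.default_factor_corr()
    names = ("AD", "CIT", "SW")
    for i in range(3):
        for j in range(i + 1, 3):
            r = np.corrcoef(dims[names[i]], dims[names[j]])[0, 1]
            assert r == pytest.approx(target[i][j], abs=0.1)


def test_weights_csv_loader(tmp_path):
    w = phenotype.synthetic_default_weights()
    df = w.reset_index()
    df.columns = ["item_id", "w_AD", "w_CIT", "w_SW"]
    path = tmp_path / "weights.csv"
    df.to_csv(path, index=False)
    back = phenotype.load_weights(path)
    assert np.allclose(back.to_numpy(), w.to_numpy())
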