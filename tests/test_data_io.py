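import numpy as np
import pandas as pd
import pytest

from cfsa import (
    Dataset,
    SyntheticSpec,
    generate_synthetic,
    read_arff_dataset,
    read_csv_dataset,
    recovery_score,
    write_csv_dataset,
)

CSV_FIXTURE = """age,sex,on_thyroxine,TSH,target
34,F,t,1.2,neg
?,M,f,2.4,pos
51,F,t,?,neg
47,M,f,0.8,pos
"""

ARFF_FIXTURE = """@relation thyroid_mini
@attribute age numeric
@attribute sex {M,F}
@attribute TSH numeric
@attribute class {neg,pos}
@data
34,F,1.2,neg
?,M,2.4,pos
51,F,?,neg
47,M,0.8,pos
"""


@pytest.fixture
def csv_path(tmp_path):
    p = tmp_path / "mini.csv"
    p.write_text(CSV_FIXTURE)
    return p


def test_csv_reader_encodes_and_imputes(csv_path):
    ds = read_csv_dataset(csv_path, "target")
    assert ds.feature_names == ["age", "sex", "on_thyroxine", "TSH"]
    assert ds.feature_kinds == ["numeric", "categorical", "boolean", "numeric"]
    age = ds.features[:, 0]
    assert age[1] == pytest.approx(47.0)  # median of 34, 51, 47
    assert ds.missing_mask[1, 0] and ds.missing_mask[2, 3]
    assert ds.missing_mask.sum() == 2
    np.testing.assert_array_equal(ds.features[:, 2], [1, 0, 1, 0])  # t/f -> 1/0
    tsh = ds.features[:, 3]
    assert tsh[2] == pytest.approx(np.median([1.2, 2.4, 0.8]))
    assert ds.meta["imputed_cells"] == 2
    assert set(ds.target) == {"neg", "pos"}


def test_csv_reader_missing_target_names_columns(csv_path):
    with pytest.raises(ValueError, match="available"):
        read_csv_dataset(csv_path, "label")


def test_csv_categorical_mapping_is_sorted(csv_path):
    ds = read_csv_dataset(csv_path, "target")
    # sex in {M, F} lower-cased -> f=0, m=1
    np.testing.assert_array_equal(ds.features[:, 1], [0, 1, 0, 1])
    assert ds.meta["encodings"]["sex"] == {"f": 0.0, "m": 1.0}


def test_csv_roundtrip_exact(csv_path, tmp_path):
    ds = read_csv_dataset(csv_path, "target")
    out = tmp_path / "encoded.csv"
    write_csv_dataset(ds, out)
    back = read_csv_dataset(out, "target")
    np.testing.assert_array_equal(ds.features, back.features)
    np.testing.assert_array_equal(ds.target.astype(str), back.target.astype(str))


def test_arff_reader_matches_contract(tmp_path):
    p = tmp_path / "mini.arff"
    p.write_text(ARFF_FIXTURE)
    ds = read_arff_dataset(p, "class")
    assert ds.feature_names == ["age", "sex", "TSH"]
    assert ds.feature_kinds == ["numeric", "categorical", "numeric"]
    assert ds.features[1, 0] == pytest.approx(47.0)  # '?' -> median
    assert ds.missing_mask[1, 0] and ds.missing_mask[2, 2]
    np.testing.assert_array_equal(ds.features[:, 1], [0, 1, 0, 1])
    assert set(ds.target) == {"neg", "pos"}
    assert "nominal" in ds.meta["arff_attributes"]["sex"]


def test_arff_malformed_raises(tmp_path):
    p = tmp_path / "bad.arff"
    p.write_text("@relation broken\n@attribute a numeric\n")
    with pytest.raises(ValueError, match="malformed|ARFF"):
        read_arff_dataset(p, "a")


def test_dataset_validation_rejects_degenerates():
    X = np.zeros((4, 2))
    base = dict(
        feature_names=["a", "b"],
        feature_kinds=["numeric", "numeric"],
        missing_mask=np.zeros((4, 2), bool),
        provenance="synthetic",
    )
    with pytest.raises(ValueError, match="2 distinct"):
        Dataset(features=X, target=np.zeros(4), **base)
    with pytest.raises(ValueError, match="n >= 2"):
        Dataset(features=np.zeros((4, 1)), target=np.array([0, 1, 0, 1]),
                feature_names=["a"], feature_kinds=["numeric"],
                missing_mask=np.zeros((4, 1), bool), provenance="synthetic")
    with pytest.raises(ValueError, match="non-finite"):
        Dataset(features=X + np.nan, target=np.array([0, 1, 0, 1]), **base)


def test_generator_reproducible():
    spec = SyntheticSpec(n=100, d=6, informative=(0,), seed=5)
    a, b = generate_synthetic(spec), generate_synthetic(spec)
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_array_equal(a.target, b.target)


def test_generator_marginals_match_effect_size():
    """Between-class mean gap of each informative feature is the effect
    size, within 3 standard errors at n=10^4."""
    spec = SyntheticSpec(n=10_000, d=4, informative=(0, 1), effect_size=2.0,
                         class_balance=0.3, seed=2)
    ds = generate_synthetic(spec)
    y = ds.target
    for j in (0, 1):
        gap = ds.features[y == 1, j].mean() - ds.features[y == 0, j].mean()
        se = np.sqrt(1 / (y == 1).sum() + 1 / (y == 0).sum())
        assert abs(gap - 2.0) < 3 * se
    # noise features stay label-independent
    for j in (2, 3):
        gap = ds.features[y == 1, j].mean() - ds.features[y == 0, j].mean()
        se = np.sqrt(1 / (y == 1).sum() + 1 / (y == 0).sum())
        assert abs(gap) < 4 * se


def test_generator_redundant_features_correlate():
    spec = SyntheticSpec(n=5000, d=6, informative=(0, 1),
                         redundant=((0, 0.9),), seed=3)
    ds = generate_synthetic(spec)
    j = spec.redundant_indices[0]
    r = np.corrcoef(ds.features[:, 0], ds.features[:, j])[0, 1]
    assert r > 0.8
    assert set(spec.informative) | {j} | set(spec.noise_indices) == set(range(6))


def test_generator_null_effect_is_label_independent():
    spec = SyntheticSpec(n=4000, d=4, informative=(0,), effect_size=0.0, seed=11)
    ds = generate_synthetic(spec)
    y = ds.target
    gap = ds.features[y == 1, 0].mean() - ds.features[y == 0, 0].mean()
    assert abs(gap) < 4 * np.sqrt(1 / (y == 1).sum() + 1 / (y == 0).sum())


def test_generator_plants_and_imputes_missing():
    spec = SyntheticSpec(n=1000, d=5, informative=(0,), missing_rate=0.1, seed=4)
    ds = generate_synthetic(spec)
    rate = ds.missing_mask.mean()
    assert 0.05 < rate < 0.15
    assert np.isfinite(ds.features).all()
    assert ds.meta["imputed_cells"] == int(ds.missing_mask.sum())


@pytest.mark.parametrize(
    "selected, expected",
    [
        ([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], (1.0, 0.0)),
        ([1] * 10, (1.0, 1.0)),
        ([1, 0, 0, 0, 0, 1, 0, 0, 0, 0], (0.5, 1 / 8)),
    ],
)
def test_recovery_score_counting(selected, expected):
    spec = SyntheticSpec(n=100, d=10, informative=(0, 1), seed=0)
    rec, fp = recovery_score(np.array(selected, bool), spec)
    assert (rec, fp) == (pytest.approx(expected[0]), pytest.approx(expected[1]))


def test_recovery_score_length_guard():
    spec = SyntheticSpec(n=100, d=10, informative=(0, 1), seed=0)
    with pytest.raises(ValueError):
        recovery_score(np.ones(5, bool), spec)


def test_synthetic_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(informative=(), d=5)
    with pytest.raises(ValueError):
        SyntheticSpec(d=5, informative=(7,))
    with pytest.raises(ValueError):
        SyntheticSpec(class_balance=0.0)
    with pytest.raises(ValueError):
        SyntheticSpec(d=5, informative=(0,), redundant=((1, 0.5),))
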