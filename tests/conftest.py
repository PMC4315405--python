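import hypothesis
import pytest

from pathoforest.synthetic import GeneratorConfig, generate_dataset

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def separable_data():
    """Well-separated synthetic benchmark (disjoint class supports)."""
    return generate_dataset(
        GeneratorConfig(seed=11, overlap=0.0, n_proteins=40, variants_per_protein=6)
    )


@pytest.fixture(scope="session")
def overlap_data():
    """Partially overlapping classes: some variants are genuinely ambiguous."""
    return generate_dataset(
        GeneratorConfig(seed=7, overlap=0.6, n_proteins=40, variants_per_protein=6)
    )


def _family_split(data, test_frac=0.25, seed=0):
    """Split a synthetic bundle into train/test without splitting families."""
    import numpy as np

    fams = data.dataset.family_ids
    rng = np.random.default_rng(seed)
    names = sorted(set(fams))
    rng.shuffle(names)
    n_test = max(1, int(len(names) * test_frac))
    test_fams = set(names[:n_test])
    test_mask = fams.isin(test_fams).to_numpy()
    X = data.features.values
    y = data.dataset.labels
    return X[~test_mask], y[~test_mask], X[test_mask], y[test_mask]


@pytest.fixture(scope="session")
def separable_split(separable_data):
    return _family_split(separable_data)


@pytest.fixture(scope="session")
def fitted_separable(separable_split):
    from pathoforest.ensemble import BootstrapForestClassifier, EnsembleConfig

    X_train, y_train, _, _ = separable_split
    model = BootstrapForestClassifier(
        X_train, y_train, config=EnsembleConfig(n_bootstrap=15, n_trees=30, seed=2),
        go_feature=None,
    )
    return model.fit()


@pytest.fixture(scope="session")
def overlap_split(overlap_data):
    return _family_split(overlap_data)


@pytest.fixture(scope="session")
def fitted_overlap(overlap_split):
    from pathoforest.ensemble import BootstrapForestClassifier, EnsembleConfig

    X_train, y_train, _, _ = overlap_split
    model = BootstrapForestClassifier(
        X_train, y_train, config=EnsembleConfig(n_bootstrap=20, n_trees=30, seed=3),
        go_feature=None,
    )
    return model.fit()


AAINDEX1_TEXT = """\
H FAKE000001
D synthetic hydropathy-like index (fixture)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.80   -4.50   -3.50   -3.50    2.50   -3.50   -3.50   -0.40   -3.20    4.50
    3.80   -3.90    1.90    2.80   -1.60   -0.80   -0.70   -0.90   -1.30    4.20
//
H FAKE000002
D synthetic index with missing values (fixture)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.10    0.20    0.30      NA    0.50    0.60    0.70    0.80    0.90    1.00
    1.10    1.20    1.30    1.40    1.50    1.60    1.70    1.80    1.90    2.00
//
H FAKE000003
D synthetic complete index (fixture)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.00    1.00    2.00    3.00    4.00    5.00    6.00    7.00    8.00    9.00
   10.00   11.00   12.00   13.00   14.00   15.00   16.00   17.00   18.00   19.00
//
"""


@pytest.fixture
def aaindex1_file(tmp_path):
    p = tmp_path / "aaindex1.txt"
    p.write_text(AAINDEX1_TEXT)
    return p


def _triangular_matrix_text(accession: str) -> str:
    """Synthetic lower-triangular AAindex2-style block with value 10*i+j."""
    order = "ARNDCQEGHILKMFPSTWYV"
    lines = [
        f"H {accession}",
        "D synthetic substitution matrix (fixture)",
        f"M rows = {order}, cols = {order}",
    ]
    for i in range(20):
        lines.append("".join(f"{i * 2.0 + j:8.1f}" for j in range(i + 1)))
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def aaindex2_file(tmp_path):
    p = tmp_path / "aaindex2.txt"
    p.write_text(_triangular_matrix_text("KOSJ950114"))
    return p


TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: middle b
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: middle c
relationship: part_of GO:0000001 ! root

[Term]
id: GO:0000004
name: leaf with two parents
is_a: GO:0000002 ! middle b
is_a: GO:0000003 ! middle c
"""


@pytest.fixture
def toy_obo_file(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p
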