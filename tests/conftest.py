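import numpy as np
import pandas as pd
import pytest

import spatialsurv as ss


@pytest.fixture(scope="session")
def palette():
    return ss.default_palette()


@pytest.fixture(scope="session")
def small_palette():
    """2 immune + 3 stromal phenotypes for exhaustive pair checks."""
    names = ("i1", "i2", "s1", "s2", "s3")
    class_of = {"i1": "immune", "i2": "immune",
                "s1": "stromal", "s2": "stromal", "s3": "stromal"}
    return ss.PhenotypePalette(names=names, class_of=class_of)


def make_image(coords, phenotypes, area=None, radius=4.0, patient_id="P1"):
    coords = np.asarray(coords, dtype=float)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(coords))],
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
            "phenotype": list(phenotypes),
        }
    )
    return ss.PatientImage(
        patient_id=patient_id, cells=cells, area_um2=area, neighbor_radius=radius
    )


@pytest.fixture
def triangle_image():
    """Three mutually adjacent cells with phenotypes (a, a, b), area 10."""
    names = ("a", "b")
    pal = ss.PhenotypePalette(names=names, class_of={"a": "immune", "b": "stromal"})
    img = make_image([(0, 0), (3, 0), (1.5, 2.5)], ["a", "a", "b"], area=10.0)
    return img, pal


def random_image(rng, n_cells=80, box=60.0, phenotypes=("a", "b", "c"), area=None,
                 radius=4.0):
    coords = rng.uniform(0, box, size=(n_cells, 2))
    labels = rng.choice(phenotypes, size=n_cells)
    return make_image(coords, labels, area=area or box * box, radius=radius)


@pytest.fixture(scope="session")
def signal_cohort(palette):
    """Shared 150-patient cohort with planted density and interaction effects."""
    effects = {
        "density|Macrophages 2": 1.2,
        "ccis|Hypoxic epithelial|Proliferative epithelial": 0.8,
    }
    cfg = ss.SimConfig(n_patients=150, seed=11, effect_vector=effects)
    cohort = ss.generate_cohort(cfg)
    matrix = ss.drop_zero_features(ss.assemble_features(cohort.images, palette))
    return cohort, matrix


@pytest.fixture(scope="session")
def fitted_twostage(signal_cohort):
    cohort, matrix = signal_cohort
    blocks = {s: matrix.subset(s) for s in ("CP", "TMI", "TCI")}
    model = ss.fit_twostage(
        blocks["CP"], blocks["TMI"], blocks["TCI"], cohort.outcome,
        l2_lambda=0.01, seed=7,
    )
    return cohort, matrix, blocks, model
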