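import numpy as np
import pandas as pd
import pytest

from prognomod.containers import ExpressionMatrix
from prognomod.modules import ModuleDefinition, ModuleRegistry


@pytest.fixture
def toy_expr():
    """6 genes x 5 samples, deterministic values."""
    rng = np.random.default_rng(7)
    genes = ["ERBB2", "ESR1", "MKI67", "AURKA", "CCNB1", "GAPDH"]
    samples = [f"S{i}" for i in range(1, 6)]
    vals = pd.DataFrame(rng.normal(8, 1, (6, 5)), index=genes, columns=samples)
    ann = pd.DataFrame(
        {"batch": ["a", "a", "a", "b", "b"],
         "platform": ["Affymetrix"] * 3 + ["Agilent"] * 2,
         "source": ["s1"] * 3 + ["s2"] * 2},
        index=samples,
    )
    return ExpressionMatrix(vals, ann)


@pytest.fixture
def toy_registry():
    """One module per scoring mode, matched to toy_expr genes."""
    return ModuleRegistry(
        [
            ModuleDefinition("prolif", ["MKI67", "AURKA", "CCNB1"], mode="median"),
            ModuleDefinition("pc_mod", ["ESR1", "MKI67", "CCNB1"], mode="first_pc"),
            ModuleDefinition(
                "subtype",
                ["ERBB2", "ESR1", "MKI67", "AURKA", "CCNB1"],
                mode="centroid_corr",
                centroids={
                    "LumA": {"ERBB2": -0.5, "ESR1": 1.0, "MKI67": -0.8, "AURKA": -0.6, "CCNB1": -0.7},
                    "Her2": {"ERBB2": 1.2, "ESR1": -0.6, "MKI67": 0.4, "AURKA": 0.5, "CCNB1": 0.3},
                },
            ),
            ModuleDefinition(
                "published",
                ["ERBB2", "ESR1", "GAPDH"],
                mode="published_model",
                weights={"ERBB2": 0.5, "ESR1": -1.0, "GAPDH": 2.0},
                offset=0.25,
            ),
        ]
    )


def make_survival_cohort(n=60, n_events=None, seed=0):
    """Small clinical+survival table for evaluation/split tests."""
    rng = np.random.default_rng(seed)
    idx = [f"P{i:03d}" for i in range(n)]
    time = rng.exponential(4.0, n) + 0.05
    event = rng.integers(0, 2, n)
    return pd.DataFrame(
        {
            "er": rng.choice(["pos", "neg"], n, p=[0.7, 0.3]),
            "size": rng.choice(["lt2cm", "ge2cm"], n),
            "grade": rng.choice(["1", "2", "3"], n),
            "her2": rng.choice(["pos", "neg"], n, p=[0.2, 0.8]),
            "source": rng.choice(["s1", "s2"], n),
            "platform": rng.choice(["Affymetrix", "Agilent"], n),
            "time": time,
            "event": event,
        },
        index=idx,
    )
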