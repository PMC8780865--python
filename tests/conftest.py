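import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_design(chemicals, concentrations, replicates, time_h=24.0):
    rows = []
    for chem in chemicals:
        for conc in concentrations:
            for r in range(1, replicates + 1):
                rows.append((f"{chem}_c{conc:g}_r{r}", chem, float(conc),
                             time_h, r))
    return pd.DataFrame(rows, columns=["sample_id", "chemical",
                                       "concentration_uM", "time_h",
                                       "replicate"])


@pytest.fixture(scope="session")
def planted_dataset():
    """Small study with 40 planted responsive genes out of 200.

    One chemical, concentrations 0/1/2 uM, 4 replicates, effect
    +1 log2FC per uM on the planted genes, dispersion <= 0.2, baselines
    >= 50: the regime in which the DE stage must be sensitive.
    """
    from hepatox.simulate import CountTruth, generate_counts

    rng = np.random.default_rng(2024)
    genes = [f"G{i:03d}" for i in range(200)]
    planted = genes[:40]
    truth = CountTruth(
        module_assignment={g: "M1" if g in planted else "M2" for g in genes},
        pathway_sets={"planted": planted},
        effect_profile={(g, "drugX"): 1.0 for g in planted},
        dispersion={g: float(rng.uniform(0.01, 0.2)) for g in genes},
        baseline_mean={g: float(np.exp(rng.uniform(np.log(50), np.log(1000))))
                       for g in genes},
    )
    design = make_design(["drugX"], [0.0, 1.0, 2.0], replicates=4)
    counts = generate_counts(truth, design, seed=77)
    return {"truth": truth, "design": design, "counts": counts,
            "planted": planted, "genes": genes}


@pytest.fixture(scope="session")
def two_block_expression():
    """Expression matrix with two strongly co-expressed 50-gene blocks."""
    rng = np.random.default_rng(11)
    n_samples = 24
    rows, truth_labels = [], []
    for block in range(2):
        latent = rng.normal(0.0, 1.0, size=n_samples)
        for _ in range(50):
            rows.append(2.0 * latent + rng.normal(0.0, 0.5, size=n_samples))
            truth_labels.append(block)
    expr = pd.DataFrame(rows, index=[f"G{i:03d}" for i in range(100)],
                        columns=[f"S{j:02d}" for j in range(n_samples)])
    return expr, np.array(truth_labels)
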