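import numpy as np
import pandas as pd
import pytest

from allelenoise import popqc, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Compact iPSC-like dataset: 40 genes, 5x4x2 populations, ASE included."""
    cfg = synthetic.SyntheticConfig(
        n_genes=40, n_donors=5, n_days=4, n_dishes=2,
        cells_per_population=40, ase_capture_rate=0.5, seed=42)
    counts, metadata, truth = synthetic.generate_counts(cfg)
    ase = synthetic.generate_ase(counts, metadata, cfg, truth)
    return {"config": cfg, "counts": counts, "metadata": metadata,
            "truth": truth, "ase": ase}


@pytest.fixture(scope="session")
def small_cpm(small_dataset):
    return popqc.cpm_normalize(small_dataset["counts"])


@pytest.fixture(scope="session")
def brain_dataset():
    cfg = synthetic.BrainConfig(seed=7)
    counts, metadata, truth = synthetic.generate_brain_like(cfg)
    return {"config": cfg, "counts": counts, "metadata": metadata,
            "truth": truth}


def metrics_from_truth(counts, metadata, truth):
    """Per-(gene, population) noise table using the generator's true bias.

    Used by recovery tests: regressing measured noise on the *true* bias
    isolates the estimator from bias-measurement attenuation.
    """
    cpm = popqc.cpm_normalize(counts)
    pop_of = metadata.set_index("cell_id")["population_id"]
    grp = cpm.T.groupby(pop_of.reindex(cpm.columns))
    mu = grp.mean().T
    eta = (grp.std(ddof=1).T / mu)
    bias = np.asarray(truth["true_bias"])
    pops = truth["population_ids"]
    day = {p: int(p.split("|")[1]) for p in pops}
    rows = []
    for gi, g in enumerate(counts.index):
        for pi, p in enumerate(pops):
            rows.append({"gene": g, "population_id": p, "eta": eta.loc[g, p],
                         "mu": mu.loc[g, p], "b": bias[gi, pi], "day": day[p]})
    return pd.DataFrame(rows)
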