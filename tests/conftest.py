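import warnings

import numpy as np
import pandas as pd
import pytest

from alpzone import qc
from alpzone.synthetic import GeneratorConfig, generate_env, generate_taxa, simulate_reads
from alpzone.tables import MOTUTable

#: the seven retained environmental variables used throughout the analysis
ENV_VARS = ["Elevation", "pH", "Nitrogen", "C_N_ratio", "FDD", "CWD", "DTR"]


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def env(config):
    return generate_env(config)


@pytest.fixture(scope="session")
def taxa(config):
    return generate_taxa(config)


@pytest.fixture(scope="session")
def simulated(env, taxa, config):
    return simulate_reads(env, taxa, config)


@pytest.fixture(scope="session")
def qc_result(simulated):
    table, pcrs = simulated
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return qc.run_qc(table, pcrs)


@pytest.fixture(scope="session")
def community(qc_result):
    return qc_result[0]


def make_table(lengths=None, counts=None, clades=None, classes=None, pcr_ids=None):
    """Small hand-built MOTU table for filter tests."""
    counts = np.atleast_2d(counts if counts is not None else np.ones((len(lengths), 2), int))
    n = counts.shape[0]
    ids = [f"M{i + 1}" for i in range(n)]
    pcr_ids = pcr_ids or [f"P{j + 1}" for j in range(counts.shape[1])]
    ann = pd.DataFrame(index=pd.Index(ids, name="motu_id"))
    if lengths is not None:
        ann["length"] = list(lengths)
    if clades is not None:
        ann["clade_path"] = list(clades)
    if classes is not None:
        ann["class"] = list(classes)
    cdf = pd.DataFrame(counts, index=ann.index, columns=pcr_ids, dtype=np.int64)
    return MOTUTable(ann, cdf)


def make_pcrs(pcr_ids, sample_ids, control_types=None, marker="Chlo01", replicates=None):
    n = len(pcr_ids)
    return pd.DataFrame(
        {
            "pcr_id": pcr_ids,
            "sample_id": sample_ids,
            "marker": marker,
            "replicate": replicates or list(range(1, n + 1)),
            "control_type": control_types or ["sample"] * n,
        }
    )
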