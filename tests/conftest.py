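import numpy as np
import pandas as pd
import pytest

from crossde.io_config import ProbesetMatrix, StudyDesign, ProbesetGeneMap
from crossde.preprocess import preprocess_experiment
from crossde import de_stats
from crossde.synthetic import SimulationConfig, generate


@pytest.fixture
def tiny_matrix():
    """2x2 example matrix: intensities [[100, 200], [50, 80]]."""
    inten = pd.DataFrame(
        [[100.0, 200.0], [50.0, 80.0]],
        index=["ps1", "ps2"],
        columns=["s1", "s2"],
    )
    calls = pd.DataFrame(
        [["P", "P"], ["A", "M"]], index=["ps1", "ps2"], columns=["s1", "s2"]
    )
    return ProbesetMatrix(intensity=inten, calls=calls)


@pytest.fixture
def invivo_design():
    return StudyDesign(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "M1", "M2", "M3", "F1", "F2", "F3"],
                "experiment": "invivo",
                "condition": ["S"] * 3 + ["M"] * 3 + ["F"] * 3,
                "pair_id": "",
            }
        )
    )


def make_matrix(intensity: np.ndarray, calls=None, prefix="ps", samples=None):
    n, m = intensity.shape
    idx = [f"{prefix}{i+1}" for i in range(n)]
    cols = samples or [f"s{j+1}" for j in range(m)]
    if calls is None:
        calls = np.full((n, m), "P")
    return ProbesetMatrix(
        intensity=pd.DataFrame(intensity, index=idx, columns=cols),
        calls=pd.DataFrame(calls, index=idx, columns=cols),
    )


SMALL_CONFIG = SimulationConfig(
    n_genes=400,
    n_program_genes=40,
    n_invivo_specific=20,
    n_invitro_specific=20,
    n_background_terms=8,
    seed=42,
)


@pytest.fixture(scope="session")
def small_study():
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_run(small_study):
    """Preprocessed matrices and differential tables for the small study."""
    st = small_study
    gm_vivo, _ = preprocess_experiment(st.invivo, st.design_invivo, st.gene_map)
    gm_vitro, _ = preprocess_experiment(st.invitro, st.design_invitro, st.gene_map)
    return {
        "study": st,
        "gm_vivo": gm_vivo,
        "gm_vitro": gm_vitro,
        "de_ms": de_stats.welch_table(gm_vivo, st.design_invivo, "S", "M"),
        "de_fm": de_stats.welch_table(gm_vivo, st.design_invivo, "M", "F"),
        "de_lps": de_stats.paired_table(
            gm_vitro, st.design_invitro, "control", "LPS"
        ),
    }
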