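import numpy as np
import pandas as pd
import pytest

from invscan import SimulationConfig, StudyDesign


def make_manual_design(
    n_lines: int,
    inverted: dict[str, list[int]],
    reps_per_sex: int = 1,
    inversions: tuple[str, ...] = ("InvX",),
) -> StudyDesign:
    """Hand-built design: ``inverted`` maps inversion -> line indices."""
    lines = [f"L{i}" for i in range(n_lines)]
    kary = pd.DataFrame(0, index=pd.Index(lines, name="line"),
                        columns=list(inversions))
    for inv, idxs in inverted.items():
        kary.loc[[lines[i] for i in idxs], inv] = 1
    rows = [
        (f"{line}_{sex}{r}", line, sex)
        for line in lines
        for sex in ("F", "M")
        for r in range(reps_per_sex)
    ]
    return StudyDesign(
        individuals=pd.DataFrame(rows, columns=["individual", "line", "sex"]),
        karyotypes=kary,
    )


@pytest.fixture
def toy_design() -> StudyDesign:
    """Two lines, one inverted, one M/F individual each: the 4-point toy."""
    return make_manual_design(2, {"InvX": [1]})


@pytest.fixture
def default_cfg() -> SimulationConfig:
    """Study-scale design but a small genome, for fast structural checks."""
    return SimulationConfig(genes_per_arm=20, snps_per_arm=20, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
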