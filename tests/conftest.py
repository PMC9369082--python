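import json

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_benchmark_dir(tmp_path):
    """A 3-drug x 2-protein benchmark directory with one missing cell.

    Affinities are stored as raw nanomolar Kd values (all > 100), so the
    loader should apply the pKd transform.
    """
    ligands = {"lig1": "CCO", "lig2": "CCN(C)C", "lig3": "c1ccccc1O"}
    proteins = {
        "prot1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
        "prot2": "MSEQNNTEMTFQIQRIYTKDISFEAPNAPHVFQ",
    }
    # rows = drugs, cols = proteins; nan = unmeasured
    y = [[10000.0, 300.0], [45.0e3, float("nan")], [7.5, 120.0]]
    d = tmp_path / "toy"
    (d / "folds").mkdir(parents=True)
    (d / "ligands_can.txt").write_text(json.dumps(ligands))
    (d / "proteins.txt").write_text(json.dumps(proteins))
    (d / "Y").write_text(
        "\n".join(" ".join(str(v) for v in row) for row in y)
    )
    # indices refer to the row-major enumeration of the 5 non-missing cells
    (d / "folds" / "train_fold_setting1.txt").write_text("[[0, 1], [2, 3]]")
    (d / "folds" / "test_fold_setting1.txt").write_text("[4]")
    return d
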