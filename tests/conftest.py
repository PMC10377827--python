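import pandas as pd
import pytest

from mirqpcr import PanelDefinition, load_panel


@pytest.fixture(scope="session")
def default_panel():
    return load_panel()


@pytest.fixture()
def tiny_panel():
    """A 6-target panel with controls, spike-in and the hemolysis pair."""
    return PanelDefinition(
        targets=(
            "hsa-miR-23a-3p",
            "hsa-miR-451a",
            "miR-A",
            "miR-B",
            "miR-C",
            "miR-D",
        ),
        endogenous_controls=("SNORD61", "RNU6B"),
        spike_in="cel-miR-39-3p",
        hemolysis_pair=("hsa-miR-23a-3p", "hsa-miR-451a"),
        name="tiny",
    )


@pytest.fixture()
def write_long_csv(tmp_path):
    """Factory writing rows of (sample, group, assay, ct) to a long CSV."""

    def _write(rows, name="ct.csv"):
        path = tmp_path / name
        frame = pd.DataFrame(rows, columns=["sample", "group", "assay", "ct"])
        frame.to_csv(path, index=False)
        return path

    return _write
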