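"""Shared fixtures: tiny in-memory libraries and file-writing helpers."""

from pathlib import Path

import pytest

from phytoscreen.library_io import CompoundRecord

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "examples" / "fixture"


@pytest.fixture
def fixture_dir() -> Path:
    return FIXTURE_DIR


@pytest.fixture
def tiny_records() -> list[CompoundRecord]:
    """A hand-built mixed library: organics, lipids, inorganics, one bad row."""
    return [
        CompoundRecord("C_01", "quercetin", "O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O", "flavonoid"),
        CompoundRecord("C_02", "ethanol", "CCO", "other"),
        CompoundRecord("C_03", "water", "O", "inorganic"),
        CompoundRecord("C_04", "salt", "[Na+].[Cl-]", "other"),
        CompoundRecord("C_05", "tributyrin", "CCCC(=O)OCC(COC(=O)CCC)OC(=O)CCC", "triacylglycerol"),
        CompoundRecord("C_06", "dg", "CCCC(=O)OCC(O)COC(=O)CCC", "diacylglycerol"),
        CompoundRecord("C_07", "pe", "CCCC(=O)OCC(COP(=O)(O)OCCN)OC(=O)CCC", "phosphatidylethanolamine"),
        CompoundRecord("C_08", "phenol", "Oc1ccccc1", "other"),
        CompoundRecord("C_09", "bad", "not_a_molecule", "other", parse_ok=False),
        CompoundRecord("C_10", "anthocyanin", "COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O", "anthocyanin"),
    ]


@pytest.fixture
def library_csv(tmp_path, tiny_records) -> Path:
    from phytoscreen.library_io import write_compound_table

    path = tmp_path / "library.csv"
    write_compound_table(tiny_records, path)
    return path
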