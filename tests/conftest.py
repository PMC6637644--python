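import pandas as pd
import pytest

from silacdiff import ProteinRecord, QuantTable


@pytest.fixture
def small_table():
    """Three clean proteins plus one contaminant, one decoy, one missing ratio."""
    records = [
        ProteinRecord("P00001", "GENA", "Protein A", 1.0),
        ProteinRecord("P00002", "GENB", "Protein B", 2.0),
        ProteinRecord("P00003", "GENC", "Protein C", 0.5),
        ProteinRecord("P00004", "GEND", "Protein D", 1.1, is_contaminant=True),
        ProteinRecord("P00005", "GENE", "Protein E", 0.9, is_reverse=True),
        ProteinRecord("P00006", "GENF", "Protein F", None),
    ]
    return QuantTable(records=records, comparison="KG1a H/M", replicate="rep1",
                      channel_scheme="heavy_over_medium")


@pytest.fixture
def protein_groups_file(tmp_path):
    """A MaxQuant-dialect proteinGroups file with the default headers."""
    df = pd.DataFrame(
        {
            "Majority protein IDs": ["P1;P1-2", "P2", "P3", "CON__P4", "REV__P5"],
            "Gene names": ["GA;GA2", "GB", "GC", "GD", "GE"],
            "Protein names": ["prot A", "prot B", "prot C", "keratin", "decoy"],
            "Ratio H/M normalized": ["1.0", "2.0", "NaN", "1.2", "0.8"],
            "Potential contaminant": ["", "", "", "+", ""],
            "Reverse": ["", "", "", "", "+"],
        }
    )
    path = tmp_path / "proteinGroups.txt"
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SET_A\tfirst set\tP1\tP2\tP3\n"
        "SET_B\tsecond set\tP2\tP4\tP5\tP6\tP6\n"
    )
    return path
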