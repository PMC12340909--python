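import gzip
import textwrap

import numpy as np
import pandas as pd
import pytest

from phosdyn import simulate

PSP_TSV = textwrap.dedent(
    """\
    Curated phosphorylation sites
    downloaded snapshot for testing

    GENE\tPROTEIN\tACC_ID\tMOD_RSD\tORGANISM\tLT_LIT\tMS_LIT\tMS_CST
    PTPN11\tSHP2\tQ06124\tY62-p\thuman\t4\t120\t230
    PTPN11\tSHP2\tQ06124\tY542-p\thuman\t60\t90\t150
    GSK3B\tGSK3B\tP49841\tY216-p\thuman\t80\t200\t300
    Ptpn11\tShp2\tP35235\tY63-p\tmouse\t2\t10\t20
    """
)


@pytest.fixture
def psp_file(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text(PSP_TSV)
    return path


@pytest.fixture
def psp_gzip_file(tmp_path):
    path = tmp_path / "sites.tsv.gz"
    with gzip.open(path, "wt") as fh:
        fh.write(PSP_TSV)
    return path


@pytest.fixture
def toy_pdb(tmp_path):
    """Single-chain 4-residue toy with one altloc pair and a water."""
    text = (
        "HEADER    TOY\n"
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA AALA A   2      12.000   6.000  -6.000  0.60  0.00           C\n"
        "ATOM      3  CA BALA A   2      12.500   6.500  -6.500  0.40  0.00           C\n"
        "ATOM      4  CA  GLY A   3      13.000   7.000  -7.000  1.00  0.00           C\n"
        "ATOM      5  CA  GLY A   4      14.000   8.000  -6.000  1.00  0.00           C\n"
        "HETATM    6  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O\n"
        "END\n"
    )
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path


def tiled_windows(segments, max_len=15, min_len=3):
    """Tile each (start, end) segment with consecutive windows of <= max_len,
    merging a too-short tail into the previous window."""
    windows = []
    for start, end in segments:
        pos = start
        while pos <= end:
            w_end = min(pos + max_len - 1, end)
            if end - w_end < min_len and w_end != end:
                w_end = end if end - pos + 1 <= max_len else w_end
            windows.append((pos, w_end))
            pos = w_end + 1
    # merge any too-short window into its predecessor when contiguous
    merged = []
    for s, e in windows:
        if merged and e - s + 1 < min_len and merged[-1][1] == s - 1:
            ps, _ = merged[-1]
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


@pytest.fixture
def planted_hdx_config():
    """Noiseless two-state HDX design with deprotected regions 3-104 and
    496-510 in the variant, peptides tiled so none straddles a boundary."""
    length = 525
    seq = simulate.random_protein_sequence(length, seed=11)
    windows = tiled_windows([(3, 104), (105, 495), (496, 510), (511, 525)])
    planted = {r: 50.0 for r in list(range(3, 105)) + list(range(496, 511))}
    return simulate.HdxSimConfig(
        protein_length=length,
        sequence=seq,
        states=["WT", "Y62D_like"],
        protection={"WT": {}, "Y62D_like": planted},
        base_protection=1e4,
        n_replicates=2,
        peptides=windows,
        centroid_noise_sd=0.0,
        seed=5,
    )
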