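"""Packaged example data.

``lung11``: the published 11-gene absolute-correlation matrix over candidate
lung adenocarcinoma biomarkers (AGER, SFTPC, TMEM100, FABP4, SPP1, WIF1,
COL11A1, CYP4B1, FCN3, ADH1B, CLDN18), stored verbatim as printed in its
source table.  The printed matrix is not perfectly symmetric (transcription
noise in a handful of mirror cells, mostly in the FABP4 and SPP1 columns),
so loading it requires an explicit asymmetry policy; the package convention
takes the upper triangle as authoritative.  The printed header also reads
"AGAR" where the accompanying gene list says AGER; the fixture uses AGER.
"""

from __future__ import annotations

from importlib import resources

from .exprdata import CorrelationNetwork, read_correlation_matrix_tsv

__all__ = ["lung11_path", "load_lung11"]

LUNG11_POLICY = "upper"


def lung11_path():
    """Filesystem path of the raw (asymmetric-as-printed) matrix TSV."""
    return resources.files("pathproxy.data") / "lung11_correlations.tsv"


def load_lung11(asymmetry_policy: str = LUNG11_POLICY) -> CorrelationNetwork:
    """The 11-gene lung biomarker correlation network.

    With the default ``upper`` policy this is the package's worked instance
    for the exact tour and tree solvers.  Passing ``error`` demonstrates
    that the printed matrix contains asymmetric cells.
    """
    with resources.as_file(lung11_path()) as p:
        return read_correlation_matrix_tsv(p, asymmetry_policy=asymmetry_policy)
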