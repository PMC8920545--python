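"""Access to the packaged fixture files.

The shipped gene-set collection is a *synthetic* stand-in for a keyword
retrieval of "osteoblast" sets from MSigDB (live database access is out of
scope): 15 sets built from canonical bone-biology gene symbols with the
category composition 1 transcription-factor / 9 differentiation /
1 development / 3 proliferation / 1 signaling. The known-gene exclusion
list is likewise an editable seed table of well-studied osteogenesis genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import GeneSetCollection, read_gmt

__all__ = ["osteoblast_collection", "known_osteogenesis_genes"]


def _data_path(name: str):
    return resources.files("osteoscreen.data").joinpath(name)


def osteoblast_collection() -> GeneSetCollection:
    """The packaged 15-set synthetic osteoblast collection."""
    with resources.as_file(_data_path("osteoblast15_synthetic.gmt")) as gmt, \
         resources.as_file(
             _data_path("osteoblast15_synthetic_categories.tsv")
         ) as cats:
        return read_gmt(gmt, cats)


def known_osteogenesis_genes() -> pd.DataFrame:
    """Editable seed list of previously studied osteogenesis genes."""
    with resources.as_file(_data_path("known_osteogenesis_genes.tsv")) as path:
        return pd.read_csv(path, sep="\t")
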