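"""Accessors for the packaged example data.

The bundled coordinate, panel and census files are synthetic stand-ins
(see each file's header): gene order matches the hg38 reference at the
loci the worked examples touch, but positions are approximate and the
panel/census lists are reconstructions, not vendor or COSMIC exports.
They make every example and test runnable offline; real analyses should
supply real files.
"""

from __future__ import annotations

import io
from importlib import resources

from .genome import GenomeIndex, load_gene_coordinates
from .panels import Panel, load_panel
from .reporting import CensusSet, load_census

__all__ = [
    "packaged_genome",
    "packaged_panel",
    "packaged_census",
]

_DATA = "ampinfer"


def _read(name: str) -> io.StringIO:
    text = (resources.files(_DATA) / "data" / name).read_text(encoding="utf-8")
    return io.StringIO(text)


def packaged_genome() -> GenomeIndex:
    """The bundled hg38-subset coordinate table (tsv5, with cytobands)."""
    return load_gene_coordinates(_read("hg38_subset.synthetic.tsv"), dialect="tsv5")


def packaged_panel() -> Panel:
    """The bundled 329-gene panel (the ``foundationone`` built-in)."""
    return load_panel("foundationone")


def packaged_census() -> CensusSet:
    """The bundled cancer gene census subset."""
    return load_census(_read("cosmic_census.synthetic.txt"))
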