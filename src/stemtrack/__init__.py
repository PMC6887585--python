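"""stemtrack: branched pseudotime analysis of tumor scRNA-seq.

End-to-end pipeline for ordering tumor cells along a branched trajectory,
extracting the stem-to-invasion path on which a stemness score falls and
an invasion score rises, and ranking the genes that switch along it.
"""

from importlib import resources

from ._types import ExpressionMatrix, SignatureSet, make_gene_map, sort_gene_map

__version__ = "0.1.0"

__all__ = [
    "ExpressionMatrix",
    "SignatureSet",
    "make_gene_map",
    "sort_gene_map",
    "default_markers",
]


def default_markers() -> SignatureSet:
    """Bundled CSC / invasive marker sets (the genes named in the text;
    any user-supplied GMT is accepted everywhere a SignatureSet is)."""
    from . import io as stio

    with resources.as_file(resources.files("stemtrack.data") / "markers.gmt") as path:
        return stio.read_gmt(str(path))
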