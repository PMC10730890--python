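"""Phenotype palettes: the controlled vocabulary of cell phenotypes.

A palette assigns each cellular phenotype to one of three broad tissue
classes — immune, stromal, epithelial — which drive the grouping of
pairwise interaction features into tumor-microenvironment (TMI) and
tumor-core (TCI) sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

CLASSES = ("immune", "stromal", "epithelial")

_IMMUNE = (
    "B cells",
    "T and B cells",
    "T cells 1",
    "Macrophages 1",
    "T cells 2",
    "Macrophages 2",
)
_STROMAL = (
    "Endothelial",
    "Vimentin-hi fibroblasts",
    "Small circular fibroblasts",
    "Small elongated fibroblasts",
    "Fibronectin-hi fibroblasts",
    "Large elongated fibroblasts",
    "SMA-hi Vimentin-hi fibroblasts",
)
_EPITHELIAL = (
    "Hypoxic epithelial",
    "Apoptotic epithelial",
    "Proliferative epithelial",
    "p53+ EGFR+ epithelial",
    "Basal CK epithelial",
    "CK7+ CK-hi Cadherin-hi epithelial",
    "CK7+ CK+ epithelial",
    "Epithelial-low",
    "CK-low HR-low epithelial",
    "CK+ HR-hi epithelial",
    "CK+ HR+ epithelial",
    "CK+ HR-low epithelial",
    "CK-low HR-hi p53+ epithelial",
    "Myoepithelial",
)


@dataclass(frozen=True)
class PhenotypePalette:
    """An ordered list of phenotype names, each mapped to a tissue class.

    Parameters
    ----------
    names
        Phenotype labels, in canonical order.
    class_of
        Mapping from each phenotype to ``"immune"``, ``"stromal"`` or
        ``"epithelial"``.
    """

    names: tuple[str, ...]
    class_of: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("palette must contain at least one phenotype")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate phenotype names in palette")
        for name in self.names:
            cls = self.class_of.get(name)
            if cls is None:
                raise ValueError(f"phenotype {name!r} has no tissue class")
            if cls not in CLASSES:
                raise ValueError(f"unknown tissue class {cls!r} for {name!r}")

    def __len__(self) -> int:
        return len(self.names)

    def members(self, cls: str) -> tuple[str, ...]:
        """Phenotypes belonging to one tissue class, in palette order."""
        return tuple(n for n in self.names if self.class_of[n] == cls)

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_palette() -> PhenotypePalette:
    """The 27-phenotype breast-tissue palette: 6 immune, 7 stromal, 14 epithelial."""
    names = _IMMUNE + _STROMAL + _EPITHELIAL
    class_of = {n: "immune" for n in _IMMUNE}
    class_of.update({n: "stromal" for n in _STROMAL})
    class_of.update({n: "epithelial" for n in _EPITHELIAL})
    return PhenotypePalette(names=names, class_of=class_of)
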