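"""Corpus-level aggregation of interaction fingerprints.

Summarizes typed contacts across many (p)ppGpp-protein complexes: counts per
interaction category, per ligand atom, per chemical moiety (guanine base,
ribose, 5'- and 3'-phosphate chains), and per functional protein class
(synthetase, nucleotide-metabolic enzyme, GTPase, RNA polymerase, riboswitch,
other).  Counts are raw contact occurrences; a per-complex-normalized mode is
available because published corpora mix very different class sizes.
Conservation is exact at every level: class, complex, atom and moiety sums
all equal the total number of contacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .interactions import CATEGORIES, Fingerprint
from .structure_io import (
    GUANINE_ATOMS,
    GAMMA_PHOSPHATE_ATOMS,
    PHOSPHATE_3PRIME_ATOMS,
    PHOSPHATE_5PRIME_ATOMS,
    RIBOSE_ATOMS,
)

__all__ = [
    "FUNCTIONAL_CLASSES",
    "MOIETIES",
    "ComplexAnnotation",
    "ClassProfile",
    "load_class_map",
    "aggregate_by_category",
    "aggregate_by_atom",
    "aggregate_by_class",
    "moiety_rollup",
    "canonical_atom_axis",
]

FUNCTIONAL_CLASSES = ("synthetase", "nucleotide_metabolic", "gtpase",
                      "rna_polymerase", "other", "riboswitch")

MOIETIES = ("guanine", "ribose", "phosphate_5prime", "phosphate_3prime")

_MOIETY_OF: dict[str, str] = {}
for _name in GUANINE_ATOMS:
    _MOIETY_OF[_name] = "guanine"
for _name in RIBOSE_ATOMS:
    _MOIETY_OF[_name] = "ribose"
for _name in PHOSPHATE_5PRIME_ATOMS + GAMMA_PHOSPHATE_ATOMS:
    _MOIETY_OF[_name] = "phosphate_5prime"
for _name in PHOSPHATE_3PRIME_ATOMS:
    _MOIETY_OF[_name] = "phosphate_3prime"


def canonical_atom_axis() -> tuple[str, ...]:
    """Full canonical (p)ppGpp atom-name axis (pppGpp superset ordering)."""
    return (GUANINE_ATOMS + RIBOSE_ATOMS + PHOSPHATE_5PRIME_ATOMS
            + GAMMA_PHOSPHATE_ATOMS + PHOSPHATE_3PRIME_ATOMS)


@dataclass(frozen=True)
class ComplexAnnotation:
    """Functional-class label of one complex."""

    pdb_id: str
    ligand_code: str = "G4P"
    functional_class: str = "other"
    source: str = "fixture"

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}; "
                             f"expected one of {FUNCTIONAL_CLASSES}")


def load_class_map(path=None) -> dict[str, str]:
    """PDB id -> functional class, from the bundled table or a user TSV.

    Duplicate ids with conflicting classes raise.
    """
    if path is None:
        text = resources.files("alarmone.data").joinpath("functional_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("pdb_id\t"):
            continue
        pdb_id, cls = (tok.strip() for tok in line.split("\t")[:2])
        if cls not in FUNCTIONAL_CLASSES:
            raise ValueError(f"class map: unknown class {cls!r} for {pdb_id}")
        if pdb_id in mapping and mapping[pdb_id] != cls:
            raise ValueError(f"class map: conflicting duplicate entry for {pdb_id}")
        mapping[pdb_id] = cls
    return mapping


def aggregate_by_category(fingerprints: Sequence[Fingerprint]) -> dict[str, int]:
    """Exact marginal contact count per interaction category over a corpus."""
    if not fingerprints:
        raise ValueError("empty corpus: no fingerprints to aggregate")
    totals = {c: 0 for c in CATEGORIES}
    for fp in fingerprints:
        for cat, n in fp.counts_by_category.items():
            totals[cat] += n
    return totals


def aggregate_by_atom(fingerprints: Sequence[Fingerprint],
                      category: str | None = None,
                      atom_axis: Sequence[str] | None = None) -> pd.Series:
    """Contact count per canonical ligand atom, optionally for one category.

    Atoms with zero contacts are reported as 0 over the full atom axis; a
    contact naming an atom outside the axis raises.
    """
    if not fingerprints:
        raise ValueError("empty corpus: no fingerprints to aggregate")
    if category is not None and category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    axis = tuple(atom_axis) if atom_axis is not None else canonical_atom_axis()
    counts = dict.fromkeys(axis, 0)
    for fp in fingerprints:
        for contact in fp.contacts:
            if category is not None and contact.category != category:
                continue
            if contact.ligand_atom not in counts:
                raise ValueError(f"unknown ligand atom name {contact.ligand_atom!r} "
                                 f"in {fp.pdb_id}")
            counts[contact.ligand_atom] += 1
    return pd.Series(counts, name=category or "all")


def moiety_rollup(fingerprint: Fingerprint) -> dict[str, dict[str, int]]:
    """Partition one fingerprint's per-atom counts into the four moieties."""
    out = {m: {c: 0 for c in CATEGORIES} for m in MOIETIES}
    for contact in fingerprint.contacts:
        moiety = _MOIETY_OF.get(contact.ligand_atom)
        if moiety is None:
            raise ValueError(f"ligand atom {contact.ligand_atom!r} belongs to no moiety")
        out[moiety][contact.category] += 1
    return out


@dataclass
class ClassProfile:
    """Per-functional-class aggregated interaction frequencies."""

    by_category: pd.DataFrame          # class x category counts
    guanine_hbonds: pd.DataFrame       # class x guanine-atom hydrogen-bond counts
    by_moiety: pd.DataFrame            # class x moiety counts
    n_complexes: dict[str, int] = field(default_factory=dict)
    normalized: bool = False

    @property
    def total(self) -> float:
        return float(self.by_category.values.sum())

    def to_dict(self) -> dict:
        return {
            "normalized": self.normalized,
            "n_complexes": self.n_complexes,
            "by_category": {c: self.by_category.loc[c].to_dict()
                            for c in self.by_category.index},
            "guanine_hbonds": {c: self.guanine_hbonds.loc[c].to_dict()
                               for c in self.guanine_hbonds.index},
            "by_moiety": {c: self.by_moiety.loc[c].to_dict()
                          for c in self.by_moiety.index},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def aggregate_by_class(fingerprints: Sequence[Fingerprint],
                       annotations: Mapping[str, ComplexAnnotation] | Iterable[ComplexAnnotation],
                       include_riboswitch: bool = False,
                       normalize: bool = False) -> ClassProfile:
    """Aggregate a corpus of fingerprints into per-functional-class profiles.

    Complexes without an annotation fall into class "other".  Riboswitch
    entries (RNA receptors) are excluded from the protein-class profile by
    default.  With ``normalize`` the counts become per-complex means within
    each class.
    """
    if not fingerprints:
        raise ValueError("empty corpus: no fingerprints to aggregate")
    if not isinstance(annotations, Mapping):
        annotations = {a.pdb_id: a for a in annotations}
    classes = [c for c in FUNCTIONAL_CLASSES if include_riboswitch or c != "riboswitch"]
    guanine = list(GUANINE_ATOMS)
    by_category = pd.DataFrame(0, index=classes, columns=list(CATEGORIES), dtype=float)
    guanine_hb = pd.DataFrame(0, index=classes, columns=guanine, dtype=float)
    by_moiety = pd.DataFrame(0, index=classes, columns=list(MOIETIES), dtype=float)
    n_complexes = dict.fromkeys(classes, 0)
    for fp in fingerprints:
        ann = annotations.get(fp.pdb_id)
        cls = ann.functional_class if ann is not None else "other"
        if cls == "riboswitch" and not include_riboswitch:
            continue
        n_complexes[cls] += 1
        for cat, n in fp.counts_by_category.items():
            by_category.loc[cls, cat] += n
        for (atom, cat), n in fp.counts_by_atom.items():
            if cat == "hbond" and atom in guanine_hb.columns:
                guanine_hb.loc[cls, atom] += n
        for moiety, cats in moiety_rollup(fp).items():
            by_moiety.loc[cls, moiety] += sum(cats.values())
    if normalize:
        for cls in classes:
            n = max(n_complexes[cls], 1)
            by_category.loc[cls] /= n
            guanine_hb.loc[cls] /= n
            by_moiety.loc[cls] /= n
    return ClassProfile(by_category=by_category, guanine_hbonds=guanine_hb,
                        by_moiety=by_moiety, n_complexes=n_complexes,
                        normalized=normalize)


def plot_class_profile(profile: ClassProfile, path) -> None:
    """Stacked bar chart of category counts per class (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = profile.by_category.plot.bar(stacked=True, figsize=(8, 4))
    ax.set_ylabel("contacts" + (" per complex" if profile.normalized else ""))
    ax.set_xlabel("functional class")
    plt.tight_layout()
    plt.savefig(path)
    plt.close()
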