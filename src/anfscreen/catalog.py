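"""Catalog of antinutritional-factor (ANF) enzyme families.

The screening pipeline is driven by a catalog of ANF *categories* (phytate
degradation, myo-inositol production, tannin degradation, ...), each holding
one or more *enzymes*.  An enzyme carries the annotation keywords used for
product-string matching, optional EC numbers (metadata only — matching never
depends on them), and optional reference protein sequences used for
alignment-based detection.

The packaged default catalog covers the eight ANF categories relevant to
plant-based-food fermentation: phytase, myo-inositol pathway, tannase,
phenolic-acid decarboxylase/UbiX, lectin, trypsin/trypsin-like protease,
beta-glucuronidase (saponin degradation) and alpha-galactosidase (alpha-GOS).
Its reference sequences are synthetic representatives (see the YAML header).

Catalog files are YAML with the schema documented in the README; a catalog
written with :func:`dump_catalog` and reloaded with :func:`load_catalog`
compares equal field by field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "EnzymeSpec",
    "ANFCategory",
    "ANFCatalog",
    "CatalogError",
    "load_catalog",
    "loads_catalog",
    "dump_catalog",
    "default_catalog",
]

#: Residues allowed in reference protein sequences.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_CATALOG_RESOURCE = "default_catalog.yaml"


class CatalogError(ValueError):
    """Raised for malformed or invariant-violating catalog definitions."""


@dataclass(frozen=True)
class EnzymeSpec:
    """One enzyme family screened for.

    Parameters
    ----------
    enzyme_id:
        Short token, unique across the whole catalog.
    name:
        Human-readable enzyme name (also used as the annotation product for
        synthetic planted genes).
    ec_numbers:
        EC strings; informational metadata only.
    product_keywords:
        Lowercase substrings matched (case-insensitively) against product
        annotations.
    reference_proteins:
        ``(ref_id, sequence)`` pairs used for alignment evidence.
    """

    enzyme_id: str
    name: str
    ec_numbers: tuple[str, ...] = ()
    product_keywords: tuple[str, ...] = ()
    reference_proteins: tuple[tuple[str, str], ...] = ()

    def validate(self) -> None:
        if not self.enzyme_id:
            raise CatalogError("enzyme with empty id")
        if not self.product_keywords and not self.reference_proteins:
            raise CatalogError(
                f"enzyme {self.enzyme_id!r}: needs at least one product keyword "
                "or one reference protein"
            )
        for kw in self.product_keywords:
            if not kw.strip():
                raise CatalogError(f"enzyme {self.enzyme_id!r}: empty keyword")
        for ref_id, seq in self.reference_proteins:
            bad = set(seq) - VALID_RESIDUES
            if not seq or bad:
                raise CatalogError(
                    f"enzyme {self.enzyme_id!r}, reference {ref_id!r}: "
                    f"invalid residues {sorted(bad) if bad else '(empty)'}"
                )


@dataclass(frozen=True)
class ANFCategory:
    """A group of enzymes acting on one antinutritional factor."""

    category_id: str
    display_name: str
    enzymes: tuple[EnzymeSpec, ...] = ()

    def validate(self) -> None:
        if not self.category_id:
            raise CatalogError("category with empty id")
        for enz in self.enzymes:
            enz.validate()


@dataclass(frozen=True)
class ANFCatalog:
    """A validated collection of ANF categories."""

    categories: tuple[ANFCategory, ...]
    version: str = "unversioned"

    def validate(self) -> None:
        seen_cat: set[str] = set()
        seen_enz: set[str] = set()
        for cat in self.categories:
            cat.validate()
            if cat.category_id in seen_cat:
                raise CatalogError(f"duplicate category id {cat.category_id!r}")
            seen_cat.add(cat.category_id)
            for enz in cat.enzymes:
                if enz.enzyme_id in seen_enz:
                    raise CatalogError(f"duplicate enzyme id {enz.enzyme_id!r}")
                seen_enz.add(enz.enzyme_id)

    # -- lookups -----------------------------------------------------------

    def iter_enzymes(self) -> Iterator[tuple[ANFCategory, EnzymeSpec]]:
        for cat in self.categories:
            for enz in cat.enzymes:
                yield cat, enz

    @property
    def category_ids(self) -> list[str]:
        return [c.category_id for c in self.categories]

    def category_of(self, enzyme_id: str) -> str:
        for cat, enz in self.iter_enzymes():
            if enz.enzyme_id == enzyme_id:
                return cat.category_id
        raise KeyError(enzyme_id)

    def enzyme(self, enzyme_id: str) -> EnzymeSpec:
        for _, enz in self.iter_enzymes():
            if enz.enzyme_id == enzyme_id:
                return enz
        raise KeyError(enzyme_id)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "categories": [
                {
                    "id": cat.category_id,
                    "name": cat.display_name,
                    "enzymes": [
                        {
                            "id": enz.enzyme_id,
                            "name": enz.name,
                            "ec": list(enz.ec_numbers),
                            "keywords": list(enz.product_keywords),
                            "references": [
                                {"id": rid, "sequence": seq}
                                for rid, seq in enz.reference_proteins
                            ],
                        }
                        for enz in cat.enzymes
                    ],
                }
                for cat in self.categories
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ANFCatalog":
        if not isinstance(data, dict) or "categories" not in data:
            raise CatalogError("catalog file must define a 'categories' list")
        cats = []
        for raw_cat in data["categories"]:
            enzymes = []
            for raw in raw_cat.get("enzymes", []):
                enzymes.append(
                    EnzymeSpec(
                        enzyme_id=str(raw["id"]),
                        name=str(raw.get("name", raw["id"])),
                        ec_numbers=tuple(str(e) for e in raw.get("ec", []) or []),
                        product_keywords=tuple(
                            str(k).lower() for k in raw.get("keywords", []) or []
                        ),
                        reference_proteins=tuple(
                            # sequences may be wrapped in the YAML; drop whitespace
                            (str(r["id"]), "".join(str(r["sequence"]).upper().split()))
                            for r in raw.get("references", []) or []
                        ),
                    )
                )
            cats.append(
                ANFCategory(
                    category_id=str(raw_cat["id"]),
                    display_name=str(raw_cat.get("name", raw_cat["id"])),
                    enzymes=tuple(enzymes),
                )
            )
        catalog = cls(
            categories=tuple(cats), version=str(data.get("version", "unversioned"))
        )
        catalog.validate()
        return catalog


def loads_catalog(text: str) -> ANFCatalog:
    """Parse a catalog from YAML text (see :func:`load_catalog`)."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise CatalogError(f"catalog parse error{line}: {exc}") from exc
    return ANFCatalog.from_dict(data)


def load_catalog(path: str | Path) -> ANFCatalog:
    """Load and validate a catalog from a YAML file.

    Raises
    ------
    CatalogError
        On YAML syntax errors (naming the line), duplicate category/enzyme
        ids, enzymes with neither keywords nor references, or invalid
        reference residues.
    FileNotFoundError
        When *path* does not exist.
    """
    return loads_catalog(Path(path).read_text())


def dump_catalog(catalog: ANFCatalog, path: str | Path) -> None:
    """Write *catalog* as YAML such that reloading round-trips exactly."""
    catalog.validate()
    Path(path).write_text(
        yaml.safe_dump(catalog.to_dict(), sort_keys=False, width=100)
    )


def default_catalog() -> ANFCatalog:
    """The packaged eight-category ANF catalog.

    Categories: phytate degradation (phytase, EC 3.1.3.8/3.1.3.26/3.1.3.72),
    myo-inositol production, tannin degradation (tannase), phenolic compounds
    (PAD/UbiX), lectin metabolism, trypsin/trypsin-like protease (EC 3.4.21.4),
    saponin degradation (beta-glucuronidase) and alpha-GOS degradation
    (alpha-galactosidase).
    """
    text = (
        resources.files("anfscreen.data")
        .joinpath(DEFAULT_CATALOG_RESOURCE)
        .read_text()
    )
    return loads_catalog(text)
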