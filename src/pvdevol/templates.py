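"""Bundled domain-template (motif) library and characterized A-domain reference table.

The library holds one canonical amino-acid template per NRPS domain kind
(C, A, T, E, TE) plus a receptor template, and the ten 1-based anchor
columns of the A-domain binding pocket (the specificity code).  The
reference table maps characterized specificity codes to their substrates.
Both ship as TSV package data so real-data users can swap them out.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

DOMAIN_KINDS = ("C", "A", "T", "E", "TE")

#: Invariant chromophore-precursor leader synthesized by PvdL, which is kept
#: outside cluster assemblies; prepend to reports if desired.
PVDL_LEADER = (("Glu", "L"), ("Tyr", "D"), ("Dab", "L"))


@dataclass(frozen=True)
class DomainTemplateLibrary:
    """Canonical template sequence per domain kind plus A-domain code columns."""

    templates: dict
    code_positions: tuple  # 1-based columns within the A template
    receptor_template: str

    def __post_init__(self):
        for kind in DOMAIN_KINDS:
            if not self.templates.get(kind):
                raise ValueError(f"empty or missing template for domain kind {kind}")
        cp = self.code_positions
        if list(cp) != sorted(set(cp)):
            raise ValueError("code positions must be strictly increasing")
        if cp[-1] > len(self.templates["A"]):
            raise ValueError("code position outside A template")

    @property
    def anchor_sequence(self) -> str:
        return self.templates["A"]

    @property
    def anchor_code(self) -> str:
        a = self.templates["A"]
        return "".join(a[p - 1] for p in self.code_positions)


@dataclass(frozen=True)
class ReferenceEntry:
    """One characterized A domain: specificity code, substrate, full sequence."""

    substrate: str
    code: str
    sequence: str
    provenance: str = ""

    def __post_init__(self):
        if len(self.code) != 10:
            raise ValueError("specificity code must have exactly 10 residues")


def _data_path(name: str):
    return resources.files("pvdevol").joinpath("data", name)


def load_template_library() -> DomainTemplateLibrary:
    df = pd.read_csv(_data_path("domain_templates.tsv"), sep="\t", dtype=str)
    rows = {r.kind: r for r in df.itertuples()}
    code = tuple(int(x) for x in rows["A"].code_positions.split(","))
    templates = {k: rows[k].sequence for k in DOMAIN_KINDS}
    return DomainTemplateLibrary(
        templates=templates,
        code_positions=code,
        receptor_template=rows["RECEPTOR"].sequence,
    )


def load_reference_table() -> list[ReferenceEntry]:
    df = pd.read_csv(_data_path("reference_adomains.tsv"), sep="\t", dtype=str)
    return [
        ReferenceEntry(r.substrate, r.code, r.full_sequence, r.provenance)
        for r in df.itertuples()
    ]


def read_reference_table(path) -> list[ReferenceEntry]:
    """Read a user-supplied reference TSV (substrate, code, full_sequence, provenance)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ReferenceEntry(r.substrate, r.code, r.full_sequence, getattr(r, "provenance", ""))
        for r in df.itertuples()
    ]


def substrate_alphabet() -> list[str]:
    return [e.substrate for e in load_reference_table()]


def normalize_substrate(name: str) -> str:
    """Normalize substrate tokens to capitalized three-plus-letter form (``Xxx`` for unknown)."""
    token = name.strip()
    if not token:
        raise ValueError("empty substrate name")
    return token[0].upper() + token[1:].lower()
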