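"""Variant panel construction: mutation specs, sequence editing, and the
13-member engineered FGF1 panel.

Every panel member shares two fixed mutation sets on top of the FGF1
scaffold — the FGFR-disrupting pair (Y94A, N95A) and the six stabilizing
substitutions (C16S, Q40P, S47I, C83S, H93G, C117S) — and differs only in
which of the four heparan-sulfate affinity mutations it carries:
A = N114R, B = S116R, C = S17K, D = L72R. The base member carrying no
affinity mutation is FGF1_HS; combinations are named by their letters
(FGF1_HS_BCD carries B, C and D).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import reference
from .numbering import ResidueNumbering, get_scheme

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution in a named numbering frame, e.g. S116R."""

    wt_residue: str
    position: int
    new_residue: str
    scheme: str = "gimenez_gallego"
    tag: str = ""

    def __post_init__(self) -> None:
        if self.wt_residue not in AMINO_ACIDS or self.new_residue not in AMINO_ACIDS:
            raise ValueError(f"invalid residue in mutation {self}")
        if self.wt_residue == self.new_residue:
            raise ValueError(f"mutation {self} does not change the residue")
        if self.position < 1:
            raise ValueError("mutation position must be >= 1")

    @classmethod
    def parse(cls, text: str, scheme: str = "gimenez_gallego",
              tag: str = "") -> "MutationSpec":
        """Parse compact notation like ``"S17K"`` (spaces tolerated)."""
        m = _MUTATION_RE.match(text.replace(" ", ""))
        if not m:
            raise ValueError(f"cannot parse mutation {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3), scheme, tag)

    @property
    def label(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"


@dataclass(frozen=True)
class VariantDefinition:
    """A named variant as three disjoint mutation sets."""

    name: str
    hs_mutations: tuple[MutationSpec, ...] = ()
    fgfr_mutations: tuple[MutationSpec, ...] = ()
    stability_mutations: tuple[MutationSpec, ...] = ()

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError(f"variant {self.name}: mutation sets overlap by position")

    @property
    def mutations(self) -> tuple[MutationSpec, ...]:
        return self.hs_mutations + self.fgfr_mutations + self.stability_mutations


def apply_mutations(sequence: str, variant: VariantDefinition,
                    scheme: "str | ResidueNumbering" = "gimenez_gallego") -> str:
    """Apply a variant's mutations to a sequence numbered in ``scheme``.

    Every wild-type residue is checked before any edit, so a numbering
    offset bug fails loudly instead of silently writing to the wrong site.
    The returned sequence has the same length and differs from the input at
    exactly as many positions as there are mutations.
    """
    sch = get_scheme(scheme)
    edits: list[tuple[int, MutationSpec]] = []
    for mut in variant.mutations:
        # positions index the *sequence* frame handed in; mutations declared
        # in another frame are converted through the parent coordinates
        if mut.scheme == sch.name:
            idx = mut.position - 1
        else:
            idx = sch.from_parent_index(
                get_scheme(mut.scheme).to_parent_index(mut.position)) - 1
        if not 0 <= idx < len(sequence):
            raise IndexError(
                f"{variant.name}: mutation {mut.label} maps outside the sequence")
        found = sequence[idx]
        if found != mut.wt_residue:
            raise ValueError(
                f"{variant.name}: expected {mut.wt_residue} at {mut.scheme} "
                f"position {mut.position} but found {found}")
        edits.append((idx, mut))
    out = list(sequence)
    for idx, mut in edits:
        out[idx] = mut.new_residue
    return "".join(out)


def make_variant(combo: str) -> VariantDefinition:
    """Panel member for an affinity-mutation combination, e.g. ``"BCD"``."""
    for letter in combo:
        if letter not in reference.HS_SITE_MUTATIONS:
            raise KeyError(f"unknown affinity-mutation label {letter!r}")
    return VariantDefinition(
        name=reference.variant_name(combo),
        hs_mutations=tuple(
            MutationSpec.parse(reference.HS_SITE_MUTATIONS[letter], tag=letter)
            for letter in combo),
        fgfr_mutations=tuple(
            MutationSpec.parse(m, tag="FGFR") for m in reference.FGFR_MUTATIONS),
        stability_mutations=tuple(
            MutationSpec.parse(m, tag="stability")
            for m in reference.STABILITY_MUTATIONS),
    )


def build_variant_panel(base: str | None = None,
                        scheme: str = "gimenez_gallego"
                        ) -> list[VariantDefinition]:
    """The 13 named panel variants, wild-type-checked against ``base``.

    ``base`` defaults to the 140-residue FGF1 sequence in Gimenez-Gallego
    numbering; pass the expression construct with ``scheme="construct"`` to
    validate against it instead.
    """
    if base is None:
        base = reference.FGF1_GG
    panel = [make_variant(combo) for combo in reference.PANEL_COMBINATIONS]
    for variant in panel:  # fail fast on any wt mismatch
        apply_mutations(base, variant, scheme=scheme)
    return panel


def panel_sequences(base: str | None = None, scheme: str = "gimenez_gallego"
                    ) -> dict[str, str]:
    """Name -> mutated sequence for the whole panel."""
    if base is None:
        base = reference.FGF1_GG
    return {v.name: apply_mutations(base, v, scheme=scheme)
            for v in build_variant_panel(base, scheme)}


def write_panel_fasta(sequences: dict[str, str], path: "str | Path") -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_mutation_manifest(panel: list[VariantDefinition],
                            path: "str | Path") -> None:
    """CSV manifest ``variant,mutation,tag,scheme`` for a panel."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variant", "mutation", "tag", "scheme"])
        for v in panel:
            for m in v.mutations:
                writer.writerow([v.name, m.label, m.tag, m.scheme])
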