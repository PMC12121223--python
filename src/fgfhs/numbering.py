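"""Residue numbering schemes and conversions for FGF1 constructs.

Three frames are in routine use for FGF1 and its engineered variants:

* ``full_length`` — the 155-residue precursor, positions 1-155;
* ``gimenez_gallego`` — the classic 140-residue form (precursor residues
  16-155), positions 1-140; all mutation labels (S17K, L72R, ...) use it;
* ``construct`` — the expressed protein, a Met-Ala leader followed by
  precursor residues 21-154, positions 1-136.

Each scheme is a bijection between its 1-based positions and 0-based
indices into the precursor sequence; conversions compose two such maps and
raise :class:`UnmappedPositionError` for positions one frame covers and the
other does not (e.g. the Met-Ala leader has no Gimenez-Gallego number, and
Gimenez-Gallego 1-5 precede the construct's first FGF1 residue).
"""

from __future__ import annotations

from dataclasses import dataclass


class UnmappedPositionError(KeyError):
    """A position exists in one numbering frame but not the other."""


@dataclass(frozen=True)
class ResidueNumbering:
    """A 1-based residue numbering frame over (part of) a parent sequence.

    Parameters
    ----------
    name:
        Scheme label, e.g. ``"gimenez_gallego"``.
    start, stop:
        Half-open 0-based slice of the parent sequence this frame covers.
        Position ``p`` (1-based) maps to parent index ``start + p - 1``.
    leader:
        Number of leading positions in this frame that do not correspond
        to any parent residue (e.g. an expression tag). Those positions
        are valid in the frame but unmapped in every other frame.
    """

    name: str
    start: int
    stop: int
    leader: int = 0

    def __post_init__(self) -> None:
        if self.stop <= self.start or self.start < 0 or self.leader < 0:
            raise ValueError("invalid numbering frame bounds")

    @property
    def length(self) -> int:
        return self.leader + (self.stop - self.start)

    def contains(self, position: int) -> bool:
        return 1 <= position <= self.length

    def to_parent_index(self, position: int) -> int:
        """0-based parent-sequence index of 1-based ``position``."""
        if not self.contains(position):
            raise UnmappedPositionError(
                f"position {position} outside {self.name} range 1..{self.length}")
        if position <= self.leader:
            raise UnmappedPositionError(
                f"{self.name} position {position} is a leader residue with "
                "no parent-sequence equivalent")
        return self.start + (position - self.leader - 1)

    def from_parent_index(self, index: int) -> int:
        """1-based position in this frame of 0-based parent index."""
        if not self.start <= index < self.stop:
            raise UnmappedPositionError(
                f"parent index {index} not covered by scheme {self.name}")
        return self.leader + (index - self.start) + 1


#: The three FGF1 frames over the 155-residue precursor.
FULL_LENGTH = ResidueNumbering("full_length", start=0, stop=155)
GIMENEZ_GALLEGO = ResidueNumbering("gimenez_gallego", start=15, stop=155)
CONSTRUCT = ResidueNumbering("construct", start=20, stop=154, leader=2)

SCHEMES = {s.name: s for s in (FULL_LENGTH, GIMENEZ_GALLEGO, CONSTRUCT)}


def get_scheme(scheme: "str | ResidueNumbering") -> ResidueNumbering:
    if isinstance(scheme, ResidueNumbering):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise KeyError(f"unknown numbering scheme {scheme!r}; "
                       f"known: {sorted(SCHEMES)}") from None


def convert_numbering(position: int,
                      from_scheme: "str | ResidueNumbering",
                      to_scheme: "str | ResidueNumbering") -> int:
    """Convert a 1-based residue position between numbering frames.

    Raises
    ------
    UnmappedPositionError
        If the position is invalid in ``from_scheme`` or the corresponding
        residue is absent from ``to_scheme`` (never silently shifted).
    """
    src = get_scheme(from_scheme)
    dst = get_scheme(to_scheme)
    return dst.from_parent_index(src.to_parent_index(position))
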