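"""Peptide-to-prohormone atlas construction.

Locates identified peptides on precursor proteins (aware of single
missense variants), computes monoisotopic masses with post-translational
modifications, annotates dibasic prohormone-convertase cleavage motifs
(KK/KR/RK/RR), and assembles per-residue coverage with abutting-peptide
junctions and functional-region overlaps.

Protein coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Monoisotopic element masses (Da).  CODATA/IUPAC values; carbon-12 exact.
_ELEMENT_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(_ELEMENT_MASS[el] * n for el, n in formula.items())


# Residue (amino acid minus water) elemental compositions.
_RESIDUE_FORMULA = {
    "G": dict(C=2, H=3, N=1, O=1),
    "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1),
    "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
}

#: Monoisotopic residue masses (Da), derived from elemental composition.
RESIDUE_MASS = {aa: _formula_mass(f) for aa, f in _RESIDUE_FORMULA.items()}

WATER_MASS = _formula_mass(dict(H=2, O=1))

#: Supported modification mass deltas (Da), Unimod-style names.  The search
#: set used for EEC peptidomics: carbamidomethyl fixed on Cys, oxidation on
#: Met, C-terminal amidation, N-terminal acetylation and pyroglutamate, plus
#: octanoyl/decanoyl for acylated ghrelin.  Numeric deltas are also accepted
#: anywhere a name is, so the table is extensible.
MODIFICATION_MASS = {
    "carbamidomethyl": _formula_mass(dict(C=2, H=3, N=1, O=1)),     # +57.0215
    "oxidation": _formula_mass(dict(O=1)),                          # +15.9949
    "amidation": _formula_mass(dict(N=1, H=1)) - _ELEMENT_MASS["O"],  # -0.9840
    "acetyl": _formula_mass(dict(C=2, H=2, O=1)),                   # +42.0106
    "pyroglutamate-from-Q": -_formula_mass(dict(N=1, H=3)),         # -17.0265
    "pyroglutamate-from-E": -_formula_mass(dict(H=2, O=1)),         # -18.0106
    "octanoyl": _formula_mass(dict(C=8, H=14, O=1)),                # +126.1045
    "decanoyl": _formula_mass(dict(C=10, H=18, O=1)),               # +154.1358
}


@dataclass(frozen=True)
class Precursor:
    """A prohormone precursor protein.

    Parameters
    ----------
    id : str
        Precursor identifier (gene or accession).
    sequence : str
        Amino-acid sequence over the 20-letter alphabet.
    variants : list of (position, ref, alt)
        Observed missense variants, 1-based; ``ref`` must match the
        sequence at ``position``.
    regions : list of (name, start, end)
        Named functional intervals, 1-based inclusive (signal peptide,
        spans aligning to characterized human peptides, ...).
    """

    id: str
    sequence: str
    variants: list[tuple[int, str, str]] = field(default_factory=list)
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty precursor sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues in {self.id!r}: {sorted(bad)}")
        for pos, ref, alt in self.variants:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"variant position {pos} outside {self.id!r}")
            if self.sequence[pos - 1] != ref:
                raise ValueError(
                    f"variant ref {ref!r} does not match sequence "
                    f"({self.sequence[pos - 1]!r}) at position {pos} of {self.id!r}"
                )
            if alt not in AMINO_ACIDS:
                raise ValueError(f"non-standard variant residue {alt!r}")
        for name, start, end in self.regions:
            if not 1 <= start <= end <= len(self.sequence):
                raise ValueError(f"region {name!r} [{start},{end}] outside {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideHit:
    """One identified peptide aligned to a precursor.

    ``modifications`` is a list of ``(position, name, mass_delta)`` where
    position is 1-based within the peptide (terminal mods sit on residue 1
    or ``len(sequence)``); ``name`` may be any key of
    :data:`MODIFICATION_MASS` or a label for an explicit numeric delta.
    ``alignment`` is the 1-based inclusive (start, end) span on the
    precursor, or ``None`` before placement.
    """

    sequence: str
    modifications: list[tuple[int, str, float]] = field(default_factory=list)
    precursor_id: str | None = None
    alignment: tuple[int, int] | None = None
    variant_used: tuple[int, str, str] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.alignment is not None:
            start, end = self.alignment
            if end - start + 1 != len(self.sequence):
                raise ValueError("alignment span length does not match peptide length")
        for pos, name, _delta in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside peptide")

    @property
    def mass(self) -> float:
        return peptide_mass(self.sequence, self.modifications)


def locate_peptide(peptide: str, precursor: Precursor) -> list[dict]:
    """Find every placement of ``peptide`` on ``precursor``.

    All (possibly overlapping) substring occurrences on the reference
    sequence are reported first; then, for each single missense variant,
    occurrences on the variant-substituted sequence whose span contains
    the variant position and which are absent from the reference.  Results
    are in deterministic left-to-right order (reference hits first, then
    variant hits ordered by variant, then position).

    Returns
    -------
    list of dict
        Each with keys ``start``, ``end`` (1-based inclusive) and
        ``variant`` (``None`` or the ``(pos, ref, alt)`` tuple used).
    """
    if not peptide:
        raise ValueError("empty peptide")
    hits: list[dict] = []
    ref_spans = set()
    for start in _substring_positions(peptide, precursor.sequence):
        hits.append({"start": start, "end": start + len(peptide) - 1, "variant": None})
        ref_spans.add(start)
    for variant in precursor.variants:
        pos, _ref, alt = variant
        mutated = precursor.sequence[: pos - 1] + alt + precursor.sequence[pos:]
        for start in _substring_positions(peptide, mutated):
            end = start + len(peptide) - 1
            if start <= pos <= end and start not in ref_spans:
                hits.append({"start": start, "end": end, "variant": variant})
    return hits


def _substring_positions(needle: str, haystack: str) -> list[int]:
    """1-based start positions of all (overlapping) occurrences."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i + 1)
        i = haystack.find(needle, i + 1)
    return out


def peptide_mass(
    sequence: str,
    modifications: list[tuple[int, str | float, float | None]] | None = None,
) -> float:
    """Monoisotopic mass (Da) of a peptide with modifications.

    mass = sum of residue masses + one water + sum of modification deltas.
    Modifications are ``(position, name, delta)`` tuples; ``delta`` may be
    ``None`` when ``name`` is in :data:`MODIFICATION_MASS`, and ``name``
    may itself be a numeric delta.
    """
    total = WATER_MASS
    for aa in sequence:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    for mod in modifications or []:
        _pos, name, *rest = mod
        delta = rest[0] if rest else None
        if delta is None:
            if isinstance(name, (int, float)):
                delta = float(name)
            elif name in MODIFICATION_MASS:
                delta = MODIFICATION_MASS[name]
            else:
                raise ValueError(f"unknown modification {name!r} with no numeric delta")
        total += delta
    return total


def ppm_match(observed: float, theoretical: float, tolerance_ppm: float = 10.0) -> bool:
    """True iff |observed - theoretical| / theoretical <= tolerance_ppm * 1e-6."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return abs(observed - theoretical) / theoretical * 1e6 <= tolerance_ppm


def find_dibasic_sites(precursor: Precursor | str) -> list[tuple[int, int]]:
    """All adjacent Lys/Arg pairs (KK, KR, RK, RR), 1-based, overlaps allowed."""
    seq = precursor.sequence if isinstance(precursor, Precursor) else precursor
    basic = frozenset("KR")
    return [
        (i + 1, i + 2)
        for i in range(len(seq) - 1)
        if seq[i] in basic and seq[i + 1] in basic
    ]


@dataclass
class PrecursorAtlas:
    """Per-residue annotation of one precursor from its aligned peptides.

    Attributes
    ----------
    coverage : ndarray of int, length = precursor length
        ``coverage[i]`` (0-based array over 1-based residues) is the
        number of aligned peptides whose span contains residue ``i + 1``.
    junctions : list of int
        Positions ``p`` where one peptide ends at ``p`` and another starts
        at ``p + 1`` — rendered as a single shared boundary line between
        abutting peptides.
    dibasic_sites : list of (int, int)
    region_overlaps : list of list of str
        For each hit (in input order), the names of precursor regions its
        span intersects.
    """

    precursor: Precursor
    hits: list[PeptideHit]
    coverage: np.ndarray
    junctions: list[int]
    dibasic_sites: list[tuple[int, int]]
    region_overlaps: list[list[str]]


def build_atlas(precursor: Precursor, hits: list[PeptideHit]) -> PrecursorAtlas:
    """Assemble coverage, junctions, cleavage sites and region overlaps."""
    n = len(precursor)
    coverage = np.zeros(n, dtype=int)
    starts: set[int] = set()
    ends: set[int] = set()
    overlaps: list[list[str]] = []
    for hit in hits:
        if hit.alignment is None:
            raise ValueError(f"peptide {hit.sequence!r} has no alignment")
        start, end = hit.alignment
        if not 1 <= start <= end <= n:
            raise ValueError(
                f"hit span ({start},{end}) outside precursor {precursor.id!r} (length {n})"
            )
        coverage[start - 1 : end] += 1
        starts.add(start)
        ends.add(end)
        overlaps.append(
            [name for name, rs, re_ in precursor.regions if start <= re_ and rs <= end]
        )
    junctions = sorted(p for p in ends if p + 1 in starts)
    return PrecursorAtlas(
        precursor=precursor,
        hits=list(hits),
        coverage=coverage,
        junctions=junctions,
        dibasic_sites=find_dibasic_sites(precursor),
        region_overlaps=overlaps,
    )
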