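"""Binarized cell-cell attraction matrix.

Adhesion between cell pairs is reduced to discrete levels: relatively weak
(sigma_W = 0.2), relatively strong (sigma_S = 0.9) and especially strong
(sigma_prime_S = 1.6). The default rule assigns weak attraction to sister
pairs (membrane-attached adhesive protein recovers slowly on the freshly
grown cytokinesis membrane) and strong attraction to non-sister pairs.
Single-pair overrides of the rule are called attraction motifs.

The matrix is dense over all unordered pairs: the force contribution of a
non-contacting pair vanishes because the neighbour gradient is zero on the
cell's support, so no contact detection is needed inside the force loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .division import Lineage
from .errors import LineageError

SIGMA_WEAK = 0.2
SIGMA_STRONG = 0.9
SIGMA_EXTRA_STRONG = 1.6

Pair = frozenset


def _pair(a: str, b: str) -> frozenset:
    if a == b:
        raise LineageError(f"no self-pair attraction: {a}")
    return frozenset((a, b))


@dataclass
class AttractionMatrix:
    """Symmetric map from unordered cell-name pairs to sigma >= 0."""

    entries: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, value in self.entries.items():
            if len(pair) != 2:
                raise LineageError(f"attraction pair must name two cells: {set(pair)}")
            if value < 0:
                raise LineageError(f"attraction must be non-negative: {set(pair)} -> {value}")

    def value(self, a: str, b: str) -> float:
        """sigma for the unordered pair (a, b); 0 for unlisted pairs."""
        return self.entries.get(_pair(a, b), 0.0)

    def with_pair(self, a: str, b: str, value: float) -> "AttractionMatrix":
        """Copy with one pair overridden (the motif operation)."""
        if value < 0:
            raise LineageError("attraction must be non-negative")
        new = dict(self.entries)
        new[_pair(a, b)] = float(value)
        return AttractionMatrix(new)

    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(sorted(p)) for p in sorted(self.entries, key=lambda p: tuple(sorted(p)))]

    def __eq__(self, other) -> bool:
        return isinstance(other, AttractionMatrix) and self.entries == other.entries


def zero_matrix(cells: Iterable[str]) -> AttractionMatrix:
    """sigma = 0 everywhere (the minimal, attraction-free model)."""
    names = list(cells)
    return AttractionMatrix(
        {_pair(a, b): 0.0 for i, a in enumerate(names) for b in names[i + 1 :]}
    )


def default_matrix(cells: Iterable[str], lin: Lineage) -> AttractionMatrix:
    """Sister rule: sigma_W for sister pairs, sigma_S for all other pairs."""
    names = list(cells)
    entries = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            entries[_pair(a, b)] = SIGMA_WEAK if lin.are_sisters(a, b) else SIGMA_STRONG
    return AttractionMatrix(entries)


def four_cell_fitted_matrix() -> AttractionMatrix:
    """The 4-cell matrix fitted to measured surface and contact areas.

    sigma = 0.9 everywhere except the EMS-P2 contact at 0.2 (the pair with
    low adhesive-protein accumulation in vivo). Dense over all 6 pairs,
    including the never-contacting ABa-P2.
    """
    cells = ["ABa", "ABp", "EMS", "P2"]
    m = zero_matrix(cells)
    entries = {p: SIGMA_STRONG for p in m.entries}
    entries[_pair("EMS", "P2")] = SIGMA_WEAK
    return AttractionMatrix(entries)


def apply_motif(m: AttractionMatrix, pair: tuple[str, str], value: float) -> AttractionMatrix:
    """Return a copy of ``m`` with the single ``pair`` set to ``value``."""
    a, b = pair
    return m.with_pair(a, b, value)


def apply_motifs(
    m: AttractionMatrix, motifs: Iterable[tuple[tuple[str, str], float]]
) -> AttractionMatrix:
    for pair, value in motifs:
        m = apply_motif(m, pair, value)
    return m
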