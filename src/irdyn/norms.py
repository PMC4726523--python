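"""Second-order social norms.

A second-order social norm is a rule used by a bystander to assign a new
reputation (Good or Bad) to a donor, based on the donor's action (cooperate
or defect) and the recipient's current reputation (Good or Bad).  It is
represented as a vector of four probabilities

    d = (d_GC, d_GD, d_BC, d_BD)

where ``d_ij`` is the probability of assigning a *Good* reputation to a
donor who took action ``j`` (C or D) toward a recipient of reputation ``i``
(G or B).  A *pure* norm has all entries in {0, 1}; there are 16 of them,
which collapse to 10 equivalence classes once the arbitrariness of the
Good/Bad labels (mirror symmetry) is taken into account.

Four pure norms have standard names:

====  ============  =================================================
name  vector        rule
====  ============  =================================================
SJ    (1, 0, 0, 1)  stern judging: Good iff C to Good or D to Bad
SS    (1, 0, 1, 1)  simple standing: any C is Good; D to Good is Bad
SH    (1, 0, 0, 0)  shunning: only C to Good is Good
IS    (1, 0, 1, 0)  image scoring: Good iff C (first-order norm)
====  ============  =================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Norm",
    "NAMED_NORMS",
    "named_norm",
    "parse_norm",
    "mirror",
    "enumerate_pure_norms",
    "equivalence_classes",
    "apply_assignment_error",
]


@dataclass(frozen=True, order=True)
class Norm:
    """Probability that a Good reputation is assigned, for each of the four
    (recipient reputation, donor action) contexts."""

    d_gc: float
    d_gd: float
    d_bc: float
    d_bd: float

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"norm entries must be probabilities, got {self.as_tuple()}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.d_gc, self.d_gd, self.d_bc, self.d_bd)

    @property
    def is_pure(self) -> bool:
        return all(v in (0.0, 1.0) for v in self.as_tuple())

    def mirror(self) -> "Norm":
        return mirror(self)

    def with_assignment_error(self, alpha: float) -> "Norm":
        return apply_assignment_error(self, alpha)

    def __str__(self) -> str:
        for name, vec in NAMED_NORMS.items():
            if self.as_tuple() == vec:
                return name
        return ",".join(format(v, "g") for v in self.as_tuple())


#: The four named pure norms (vectors verified against their verbal rules).
NAMED_NORMS: dict[str, tuple[float, float, float, float]] = {
    "SJ": (1.0, 0.0, 0.0, 1.0),
    "SS": (1.0, 0.0, 1.0, 1.0),
    "SH": (1.0, 0.0, 0.0, 0.0),
    "IS": (1.0, 0.0, 1.0, 0.0),
}


def named_norm(name: str) -> Norm:
    """Return one of the four named norms (case-insensitive).

    Raises
    ------
    KeyError
        If ``name`` is not one of SJ, SS, SH, IS.
    """
    key = name.strip().upper()
    try:
        return Norm(*NAMED_NORMS[key])
    except KeyError:
        raise KeyError(
            f"unknown norm name {name!r}; valid names are {sorted(NAMED_NORMS)}"
        ) from None


def parse_norm(text: str) -> Norm:
    """Parse a norm from a name (``"SJ"``) or four comma-separated floats
    (``"1,0,0,1"``)."""
    if text.strip().upper() in NAMED_NORMS:
        return named_norm(text)
    parts = text.split(",")
    if len(parts) != 4:
        raise ValueError(
            f"cannot parse norm {text!r}: expected a name in {sorted(NAMED_NORMS)} "
            "or 4 comma-separated probabilities"
        )
    return Norm(*(float(p) for p in parts))


def mirror(norm: Norm) -> Norm:
    """Swap the Good/Bad labels: d -> (1-d_BC, 1-d_BD, 1-d_GC, 1-d_GD).

    Two norms related by this involution produce identical dynamics up to a
    relabelling of reputations (and the induced swap Disc <-> pDisc of the
    discriminating strategies).
    """
    return Norm(1 - norm.d_bc, 1 - norm.d_bd, 1 - norm.d_gc, 1 - norm.d_gd)


def enumerate_pure_norms() -> list[Norm]:
    """All 16 pure second-order norms, ordered as 4-bit strings
    (d_GC, d_GD, d_BC, d_BD) counting from (0,0,0,0) to (1,1,1,1)."""
    return [
        Norm(float(b >> 3 & 1), float(b >> 2 & 1), float(b >> 1 & 1), float(b & 1))
        for b in range(16)
    ]


def equivalence_classes(norms: Iterable[Norm] | None = None) -> list[frozenset[Norm]]:
    """Partition pure norms into classes under mirror symmetry.

    With the Good/Bad labels interchangeable, the 16 pure norms reduce to 10
    distinct classes (4 self-mirror singletons and 6 pairs).  Classes are
    sorted by their lexicographically smallest member, which serves as the
    canonical representative.
    """
    pool: Sequence[Norm] = list(norms) if norms is not None else enumerate_pure_norms()
    seen: set[Norm] = set()
    classes: list[frozenset[Norm]] = []
    for n in pool:
        if n in seen:
            continue
        cls = frozenset({n, mirror(n)})
        seen |= cls
        classes.append(cls)
    return sorted(classes, key=lambda c: min(c))


def apply_assignment_error(norm: Norm, alpha: float) -> Norm:
    """Fold the bystander's assignment error into the norm: d -> (1-2a)d + a.

    With probability ``alpha`` the bystander records the opposite of the
    reputation the norm prescribes, so each entry is shrunk toward 1/2.
    ``alpha`` must lie in [0, 0.5]; beyond 0.5 the transform would invert
    the norm's meaning.
    """
    if not 0.0 <= alpha <= 0.5:
        raise ValueError(f"assignment error alpha must be in [0, 0.5], got {alpha}")
    return Norm(*((1 - 2 * alpha) * v + alpha for v in norm.as_tuple()))
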