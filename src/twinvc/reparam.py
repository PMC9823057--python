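"""Closed-form twin-study summaries: Falconer estimates and ACE<->ADE moves.

The classical twin design cannot estimate shared environment (C) and
dominance (D) simultaneously; fitting the ACE model with unbounded
variance components makes the two decompositions interconvertible by exact
arithmetic on the standardized shares:

* ACE -> ADE:  a2' = a2 + 3 c2,   d2 = -2 c2,   e2 unchanged
* ADE -> ACE:  a2' = a2 + 1.5 d2, c2 = -0.5 d2, e2 unchanged

Both maps preserve e2 and the sum-to-one constraint exactly and are
mutual inverses.
"""

from __future__ import annotations

from dataclasses import dataclass

_SUM_TOL = 1e-10


@dataclass(frozen=True)
class ComponentShares:
    """Standardized variance shares under one parameterization.

    ``familial`` is c2 under the ACE tag and d2 under the ADE tag; it may
    be negative under direct (unbounded) estimation, where negative c2
    reads as non-additive genetic variance outweighing shared environment.
    """

    a2: float
    familial: float
    e2: float
    tag: str  # "ACE" or "ADE"

    def __post_init__(self) -> None:
        if self.tag not in ("ACE", "ADE"):
            raise ValueError(f"tag must be 'ACE' or 'ADE', got {self.tag!r}")
        total = self.a2 + self.familial + self.e2
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"shares must sum to 1 (got {total!r})")

    @property
    def c2(self) -> float:
        if self.tag != "ACE":
            raise AttributeError("c2 is defined only under the ACE tag")
        return self.familial

    @property
    def d2(self) -> float:
        if self.tag != "ADE":
            raise AttributeError("d2 is defined only under the ADE tag")
        return self.familial

    def to_raw(self, total_variance: float) -> dict[str, float]:
        """Raw-scale components obtained by scaling through the total."""
        key = "C" if self.tag == "ACE" else "D"
        return {
            "A": self.a2 * total_variance,
            key: self.familial * total_variance,
            "E": self.e2 * total_variance,
        }


def ace_shares(a2: float, c2: float, e2: float) -> ComponentShares:
    return ComponentShares(a2=a2, familial=c2, e2=e2, tag="ACE")


def ade_shares(a2: float, d2: float, e2: float) -> ComponentShares:
    return ComponentShares(a2=a2, familial=d2, e2=e2, tag="ADE")


def falconer(r_mz: float, r_dz: float) -> ComponentShares:
    """Falconer moment estimates: h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ,
    e2 = 1 - rMZ."""
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
    return ace_shares(2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz)


def ace_to_ade(shares: ComponentShares) -> ComponentShares:
    """Reparameterize ACE shares as the equivalent ADE shares."""
    if shares.tag != "ACE":
        raise ValueError("input must carry the ACE tag")
    return ade_shares(shares.a2 + 3.0 * shares.c2, -2.0 * shares.c2, shares.e2)


def ade_to_ace(shares: ComponentShares) -> ComponentShares:
    """Reparameterize ADE shares as the equivalent ACE shares."""
    if shares.tag != "ADE":
        raise ValueError("input must carry the ADE tag")
    return ace_shares(shares.a2 + 1.5 * shares.d2, -0.5 * shares.d2, shares.e2)
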