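"""Decay data and decay arithmetic for the astatine-211 chain.

211At disintegrates along two branches: direct alpha emission to 207Bi
(5.8695 MeV), or electron capture to 211Po, which alpha-decays to stable
207Pb (7.4503 MeV) with a half-life of ~0.52 s — effectively instantaneous
at the hour scale of an antibody biodistribution. Dosimetry therefore uses
a single branching-ratio-weighted alpha energy per parent decay.

Branch fractions, alpha energies and half-lives are embedded as versioned
package constants sourced from the MIRD/ENSDF decay schemes
(``data/at211_chain.csv``); an alternative constants file can be supplied.
Only alpha energy is tracked: electron, photon and X-ray emissions are
outside the local-energy-deposition dose model used here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ValidationError

__all__ = [
    "DecayBranch",
    "NuclideChain",
    "load_chain",
    "decay_constant",
    "decay_factor",
    "mean_alpha_energy_per_decay",
    "AT211",
]

#: tolerance on the sum of a parent's branch fractions
_BRANCH_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DecayBranch:
    """One disintegration branch of a parent nuclide.

    ``alpha_energy`` is the alpha-particle energy released in this branch in
    MeV; 0.0 for branches with no alpha emission (e.g. electron capture).
    """

    parent: str
    daughter: str
    branch_fraction: float
    alpha_energy: float  # MeV

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_fraction <= 1.0:
            raise ValidationError(
                f"branch fraction {self.branch_fraction} outside [0, 1] "
                f"for {self.parent} -> {self.daughter}"
            )
        if self.alpha_energy < 0.0:
            raise ValidationError(
                f"negative alpha energy for {self.parent} -> {self.daughter}"
            )


@dataclass(frozen=True)
class NuclideChain:
    """A decay chain rooted at ``nuclide`` with half-life in hours.

    ``branches`` holds every branch of the chain (root and daughters);
    nuclides with no outgoing branch are terminal. The chain must be
    acyclic and every stored parent's fractions must sum to 1.
    """

    nuclide: str
    half_life: float  # hours
    branches: tuple[DecayBranch, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.half_life > 0.0 and math.isfinite(self.half_life)):
            raise ValidationError(f"half-life must be positive and finite, got {self.half_life}")
        sums: dict[str, float] = {}
        for b in self.branches:
            sums[b.parent] = sums.get(b.parent, 0.0) + b.branch_fraction
        for parent, s in sums.items():
            if abs(s - 1.0) > _BRANCH_SUM_TOL:
                raise ValidationError(f"branch fractions of {parent} sum to {s!r}, not 1")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: dict[str, list[str]] = {}
        for b in self.branches:
            children.setdefault(b.parent, []).append(b.daughter)
        seen: set[str] = set()

        def visit(node: str, path: set[str]) -> None:
            if node in path:
                raise ValidationError(f"decay chain contains a cycle through {node}")
            if node in seen:
                return
            seen.add(node)
            for child in children.get(node, ()):
                visit(child, path | {node})

        visit(self.nuclide, set())

    def branches_of(self, parent: str) -> tuple[DecayBranch, ...]:
        return tuple(b for b in self.branches if b.parent == parent)


def decay_constant(half_life: float) -> float:
    """Return the decay rate lambda = ln(2)/T1/2 in h^-1 for T1/2 in hours."""
    if not (half_life > 0.0 and math.isfinite(half_life)):
        raise ValidationError(f"half-life must be positive and finite, got {half_life}")
    return math.log(2.0) / half_life


def decay_factor(t: float, lam: float) -> float:
    """Fraction of activity remaining after ``t`` hours at rate ``lam`` (h^-1)."""
    if t < 0.0:
        raise ValidationError(f"time must be non-negative, got {t}")
    if lam < 0.0:
        raise ValidationError(f"decay constant must be non-negative, got {lam}")
    return math.exp(-lam * t)


def mean_alpha_energy_per_decay(chain: NuclideChain) -> float:
    """Branching-ratio-weighted alpha energy per decay of the chain root, MeV.

    Sums, over every branch reachable from the root, the probability of the
    decay path reaching that branch times its alpha energy. Short-lived
    daughters (211Po, T1/2 ~ 0.52 s) are treated as in secular equilibrium
    with the parent, so their alpha is credited to the parent decay. For the
    default 211At chain this evaluates to 6.79 MeV (2 decimals).
    """
    if not chain.branches:
        raise ValidationError("chain has no branches")
    total = 0.0
    # stack of (nuclide, probability of having reached it)
    stack: list[tuple[str, float]] = [(chain.nuclide, 1.0)]
    while stack:
        node, prob = stack.pop()
        for b in chain.branches_of(node):
            p = prob * b.branch_fraction
            total += p * b.alpha_energy
            stack.append((b.daughter, p))
    return total


def load_chain(path: str | Path | None = None) -> NuclideChain:
    """Load a decay chain from a constants CSV.

    The file has one branch per row with columns
    ``parent,daughter,branch_fraction,alpha_energy_mev,parent_half_life_h``;
    the first row's parent is taken as the chain root. Defaults to the
    embedded 211At table.
    """
    if path is None:
        ref = resources.files("atdosim.data").joinpath("at211_chain.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.DictReader(text.splitlines()))
    if not rows:
        raise ValidationError("nuclide constants file has no branch rows")
    branches = tuple(
        DecayBranch(
            parent=r["parent"],
            daughter=r["daughter"],
            branch_fraction=float(r["branch_fraction"]),
            alpha_energy=float(r["alpha_energy_mev"]),
        )
        for r in rows
    )
    root = rows[0]["parent"]
    half_life = float(rows[0]["parent_half_life_h"])
    return NuclideChain(nuclide=root, half_life=half_life, branches=branches)


#: the default embedded astatine-211 chain
AT211: NuclideChain = load_chain()
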