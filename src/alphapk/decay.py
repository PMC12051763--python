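"""Decay-chain physics for in-vivo alpha-generator radionuclides.

²¹²Pb is an in-vivo α-generator: it emits no α-particle itself but feeds
the short-lived α-emitter ²¹²Bi, which decays through the branched
²⁰⁸Tl / ²¹²Po routes to stable ²⁰⁸Pb, delivering exactly one α-particle
per ²¹²Pb decay.  This module holds the bundled nuclear data (half-lives,
branchings, mean emission energies), the Bateman chain arithmetic, the
well-counter counting-window correction, and the effective/biologic
half-life algebra that the clearance, blood and dose-scaling layers
build on.

Units: time in hours, activity in MBq, emission energies in keV
(returned chain sums in MeV).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

LN2 = math.log(2.0)

EMISSION_KINDS = ("alpha", "beta_mean", "gamma", "xray")


class NuclideDataError(KeyError):
    """Bundled decay data does not cover a requested nuclide."""


@dataclass(frozen=True)
class Emission:
    """A single emission type with mean energy and per-decay intensity.

    ``beta_mean`` entries carry the mean electron energy per decay
    (β plus conversion/Auger electrons); α entries carry branch-weighted
    mean α energies.
    """

    kind: str
    energy_keV: float
    intensity: float

    def __post_init__(self) -> None:
        if self.kind not in EMISSION_KINDS:
            raise ValueError(f"unknown emission kind {self.kind!r}")
        if self.energy_keV <= 0:
            raise ValueError("emission energy must be positive")
        if self.intensity < 0:
            raise ValueError("emission intensity must be non-negative")


@dataclass(frozen=True)
class Nuclide:
    """A nuclide with half-life, emissions and decay branches.

    ``half_life_h`` is ``None`` for stable nuclides.  ``daughters`` maps
    daughter names to branching fractions; they must sum to 1 for
    radioactive nuclides (within rounding) and be empty for stable ones.
    """

    name: str
    half_life_h: float | None
    emissions: tuple[Emission, ...] = ()
    daughters: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.half_life_h is not None and self.half_life_h <= 0:
            raise ValueError(f"{self.name}: half-life must be positive")
        total = sum(f for _, f in self.daughters)
        if total > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: branching fractions sum to {total} > 1")
        if self.stable and self.daughters:
            raise ValueError(f"{self.name}: stable nuclide cannot have daughters")

    @property
    def stable(self) -> bool:
        return self.half_life_h is None

    @property
    def decay_constant(self) -> float:
        """λ in 1/h; 0 for stable nuclides."""
        return 0.0 if self.stable else LN2 / self.half_life_h


def _load_bundled() -> dict[str, Nuclide]:
    raw = json.loads(
        resources.files("alphapk.data").joinpath("nuclides.json").read_text()
    )
    table: dict[str, Nuclide] = {}
    for rec in raw["nuclides"]:
        table[rec["name"]] = Nuclide(
            name=rec["name"],
            half_life_h=rec["half_life_h"],
            emissions=tuple(
                Emission(e["kind"], e["energy_keV"], e["intensity"])
                for e in rec["emissions"]
            ),
            daughters=tuple((d["name"], d["fraction"]) for d in rec["daughters"]),
        )
    return table


_NUCLIDES: dict[str, Nuclide] | None = None


def nuclide(name: str) -> Nuclide:
    """Look up a nuclide in the bundled decay-data table."""
    global _NUCLIDES
    if _NUCLIDES is None:
        _NUCLIDES = _load_bundled()
    try:
        return _NUCLIDES[name]
    except KeyError:
        raise NuclideDataError(
            f"nuclide {name!r} not present in bundled decay data"
        ) from None


@dataclass
class DecayChain:
    """A decay chain rooted at ``parent`` with a given initial activity.

    The chain is the set of nuclides reachable from the parent through
    the bundled branching data; it must be acyclic and terminate at a
    stable nuclide.  ``members`` lists nuclides in topological order.
    """

    parent: str
    initial_activity_MBq: float = 1.0
    members: list[Nuclide] = field(init=False)

    def __post_init__(self) -> None:
        if self.initial_activity_MBq < 0:
            raise ValueError("initial activity must be non-negative")
        order: list[Nuclide] = []
        seen: set[str] = set()

        def visit(name: str, stack: tuple[str, ...]) -> None:
            if name in stack:
                raise ValueError(f"decay chain contains a cycle at {name}")
            if name in seen:
                return
            nuc = nuclide(name)
            for dname, _ in nuc.daughters:
                visit(dname, stack + (name,))
            seen.add(name)
            order.append(nuc)

        visit(self.parent, ())
        order.reverse()
        self.members = order
        if not any(n.stable for n in order):
            raise ValueError(f"chain from {self.parent} does not reach a stable nuclide")

    def reach_probability(self, name: str) -> float:
        """Probability that a decay of the parent eventually passes through ``name``."""
        probs = {self.parent: 1.0}
        for nuc in self.members:
            p = probs.get(nuc.name, 0.0)
            for dname, frac in nuc.daughters:
                probs[dname] = probs.get(dname, 0.0) + p * frac
        if name not in probs:
            raise NuclideDataError(f"{name} is not part of the {self.parent} chain")
        return probs[name]

    def paths(self) -> Iterable[tuple[list[Nuclide], float]]:
        """All decay paths from parent to every member, with branch products."""
        stack: list[tuple[list[Nuclide], float]] = [([nuclide(self.parent)], 1.0)]
        while stack:
            path, frac = stack.pop()
            yield path, frac
            for dname, dfrac in path[-1].daughters:
                stack.append((path + [nuclide(dname)], frac * dfrac))


def decay_factor(half_life: float, dt: float) -> float:
    """Fraction of activity remaining after ``dt`` hours, ``2^(−dt/T½)``.

    Raises ``ValueError`` for non-positive half-life or negative ``dt``.
    """
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    if dt < 0:
        raise ValueError("elapsed time must be non-negative")
    return 2.0 ** (-dt / half_life)


def _bateman_path(lambdas: Sequence[float], a0: float, t: float) -> float:
    """Activity of the last member of a serial path at time t.

    Standard Bateman solution for N0 atoms of the first member; repeated
    decay constants are split by a tiny relative perturbation so the
    distinct-λ formula stays valid (error ~1e-7 relative, far below the
    oracle tolerance used in the tests).
    """
    lam = np.array(lambdas, dtype=float)
    if lam[-1] == 0.0:  # stable end member: no activity
        return 0.0
    # perturb near-degenerate pairs
    for i in range(1, len(lam)):
        for j in range(i):
            if lam[j] != 0 and abs(lam[i] - lam[j]) < 1e-9 * max(lam[i], lam[j]):
                lam[i] *= 1.0 + 1e-7
    n0 = a0 / lam[0]  # atoms of the parent
    acts = 0.0
    prod_lam = np.prod(lam[:-1]) if len(lam) > 1 else 1.0
    for j, lj in enumerate(lam):
        denom = 1.0
        for m, lm in enumerate(lam):
            if m != j:
                denom *= lm - lj
        acts += math.exp(-lj * t) / denom
    return lam[-1] * n0 * prod_lam * acts if len(lam) > 1 else a0 * math.exp(-lam[0] * t)


def bateman_activities(chain: DecayChain, t: float) -> dict[str, float]:
    """Activity of every chain member at time ``t`` (hours), in MBq.

    Closed-form Bateman solution for a linear chain with branching,
    obtained by summing over all decay paths from the parent; only the
    parent carries activity at t=0.  Stable end members have activity 0.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    a0 = chain.initial_activity_MBq
    result = {n.name: 0.0 for n in chain.members}
    if t == 0.0:  # exact initial condition, avoids cancellation dust
        result[chain.parent] = a0
        return result
    for path, frac in chain.paths():
        lambdas = [n.decay_constant for n in path]
        result[path[-1].name] += frac * max(_bateman_path(lambdas, a0, t), 0.0)
    return result


def counting_window_correction(
    delay: float, duration: float, half_life: float
) -> float:
    """Factor converting a mean count rate over an acquisition window back
    to activity at sampling time.

    A sample counted from ``delay`` to ``delay + duration`` hours after
    sampling yields a mean rate proportional to the time-averaged
    activity over the window; the correction is

        e^(λ·delay) · λ·duration / (1 − e^(−λ·duration)),

    which is ≥ 1 and strictly increasing in both delay and duration.
    ``duration → 0`` recovers the pure decay correction ``e^(λ·delay)``.
    """
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    lam = LN2 / half_life
    delay_part = math.exp(lam * delay)
    x = lam * duration
    if x == 0.0:
        return delay_part
    return delay_part * x / (-math.expm1(-x))


def total_emitted_energy(
    chain: DecayChain, kinds: Iterable[str] = ("alpha", "beta_mean")
) -> float:
    """Branching-weighted mean energy (MeV) emitted per parent decay.

    Sums ``energy × intensity`` over the requested emission kinds for
    every chain member, weighted by the probability that a parent decay
    reaches that member.  With ``kinds=("alpha",)`` on the ²¹²Pb chain
    this is the one-α-per-decay budget (~7.8 MeV).
    """
    kinds = set(kinds)
    unknown = kinds - set(EMISSION_KINDS)
    if unknown:
        raise ValueError(f"unknown emission kinds: {sorted(unknown)}")
    total_keV = 0.0
    for nuc in chain.members:
        if nuc.stable:
            continue
        w = chain.reach_probability(nuc.name)
        total_keV += w * sum(
            e.energy_keV * e.intensity for e in nuc.emissions if e.kind in kinds
        )
    return total_keV / 1000.0


def effective_half_life(t_phys: float, t_bio: float) -> float:
    """Combine physical and biologic half-lives: 1/T_eff = 1/T_phys + 1/T_bio."""
    if t_phys <= 0 or t_bio <= 0:
        raise ValueError("half-lives must be positive")
    return 1.0 / (1.0 / t_phys + 1.0 / t_bio)


def biologic_half_life(t_eff: float, t_phys: float) -> float:
    """Invert the effective-half-life relation; requires T_eff < T_phys."""
    if t_eff <= 0 or t_phys <= 0:
        raise ValueError("half-lives must be positive")
    if t_eff >= t_phys:
        raise ValueError("effective half-life must be shorter than physical")
    return 1.0 / (1.0 / t_eff - 1.0 / t_phys)


PB212 = "Pb-212"
AC225 = "Ac-225"
PB212_HALF_LIFE_H = 10.64
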