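"""Per-step stochastic chemistry of small molecules.

The reaction network is a pair of reversible chains plus the amphiphile
branch::

    Npp <-> Np <-> Nt(A|U|G|C)        Ap <-> Am (free or in membrane)

Forward ("synthetic") steps may be catalysed by a ribozyme present in the
same compartment: Npsr for Npp->Np, Nsr for Np->Nt, Asr for Ap->Am.
Catalysis is presence-based -- one active ribozyme switches every eligible
substrate in its compartment to the catalysed probability for that step --
and never changes which transformations are possible.  Degradative steps
(nucleotide, precursor and amphiphile decay) run ``F_DO`` times faster
outside protocells, where the water activity is higher.

Each molecule attempts at most one transformation per step: competing fates
of one pool are drawn as a single multinomial split of the pool count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterSet, WorldState

__all__ = [
    "ReactionContext",
    "RoomPools",
    "effective_probability",
    "step_small_molecules",
    "chemistry_phase",
]

RIBOZYME_ROLES = ("Rep", "Nsr", "Npsr", "Asr")


@dataclass
class ReactionContext:
    """Where a reaction happens and which catalysts are around."""

    inside_protocell: bool = False
    catalysts_present: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.catalysts_present) - set(RIBOZYME_ROLES)
        if unknown:
            raise ValueError(f"unknown ribozyme roles: {sorted(unknown)}")


def effective_probability(
    base_p: float,
    catalyzed_p: float | None,
    role_needed: str | None,
    context: ReactionContext,
    degradative: bool,
    F_DO: float,
) -> float:
    """Per-molecule probability of an event given catalysis and location.

    The catalysed probability replaces the base one when the needed
    ribozyme role is present in the same compartment; degradative events
    outside any protocell are multiplied by ``F_DO``.  The result is
    clamped to [0, 1].
    """
    p = base_p
    if role_needed is not None and catalyzed_p is not None \
            and role_needed in context.catalysts_present:
        p = catalyzed_p
    if degradative and not context.inside_protocell:
        p = p * F_DO
    return min(max(p, 0.0), 1.0)


@dataclass
class RoomPools:
    """Small-molecule counts of a single compartment (for the per-room API)."""

    npp: int = 0
    np_: int = 0
    nt: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    ap: int = 0
    am_free: int = 0
    am_membrane: int = 0

    def nucleotide_equivalents(self) -> int:
        return int(self.npp + self.np_ + self.nt.sum())

    def amphiphile_equivalents(self) -> int:
        return int(self.ap + self.am_free + self.am_membrane)


def _split_two(rng: np.random.Generator, n, p1, p2):
    """Multinomial split of counts ``n`` into (event1, event2, neither).

    ``p1 + p2`` is clamped to 1; each molecule undergoes at most one of the
    two competing transformations.
    """
    n = np.asarray(n, dtype=np.int64)
    p1 = np.minimum(p1, 1.0)
    k1 = rng.binomial(n, p1)
    rest = np.where(p1 < 1.0, p2 / np.maximum(1.0 - p1, 1e-300), 0.0)
    k2 = rng.binomial(n - k1, np.minimum(rest, 1.0))
    return k1, k2


def _chem_step_arrays(
    rng: np.random.Generator,
    params: ParameterSet,
    npp, np_, nt, ap, am_free, am_memb,
    inside, npsr, nsr, asr,
):
    """Vectorised single chemistry step over parallel room arrays.

    All inputs are arrays over rooms (``nt`` has a trailing base axis);
    ``inside``/``npsr``/``nsr``/``asr`` are boolean masks.  Returns the
    updated pools; totals are conserved exactly.
    """
    fdo = np.where(inside, 1.0, params.F_DO)

    p_npf = np.where(npsr, params.P_NPFR, params.P_NPF)
    p_nf = np.where(nsr, params.P_NFR, params.P_NF)
    p_af = np.where(asr, params.P_AFR, params.P_AF)
    p_nd = np.minimum(params.P_ND * fdo, 1.0)
    p_npd = np.minimum(params.P_NPD * fdo, 1.0)
    p_ad = np.minimum(params.P_AD * fdo, 1.0)

    # All draws are taken on the entry counts, then applied at once, so a
    # molecule formed this step cannot transform again within the step.
    npp_up = rng.binomial(npp, p_npf)                       # Npp -> Np
    np_up, np_down = _split_two(rng, np_, p_nf, p_npd)      # Np -> Nt | Npp
    nt_down = rng.binomial(nt, p_nd[:, None])               # Nt -> Np
    ap_up = rng.binomial(ap, p_af)                          # Ap -> Am
    am_down = rng.binomial(am_free, p_ad)                   # Am(free) -> Ap
    memb_down = rng.binomial(am_memb, min(params.P_ADM, 1.0))  # membrane decay

    # New nucleotides pick their base uniformly: 4-way multinomial split.
    b0 = rng.binomial(np_up, 0.25)
    rem = np_up - b0
    b1 = rng.binomial(rem, 1.0 / 3.0)
    rem = rem - b1
    b2 = rng.binomial(rem, 0.5)
    b3 = rem - b2
    new_nt = np.stack([b0, b1, b2, b3], axis=-1)

    npp_new = npp - npp_up + np_down
    np_new = np_ - np_up - np_down + npp_up + nt_down.sum(axis=-1)
    nt_new = nt - nt_down + new_nt
    ap_new = ap - ap_up + am_down + memb_down
    am_new = am_free - am_down + ap_up
    memb_new = am_memb - memb_down
    return npp_new, np_new, nt_new, ap_new, am_new, memb_new


def step_small_molecules(
    pools: RoomPools,
    params: ParameterSet,
    context: ReactionContext,
    rng: np.random.Generator,
) -> RoomPools:
    """One chemistry step for a single compartment's pools.

    Thin scalar wrapper around the vectorised kernel used by the world
    stepper; returns a new :class:`RoomPools`.
    """
    one = lambda v: np.asarray([v], dtype=np.int64)
    mask = lambda flag: np.asarray([flag], dtype=bool)
    cats = context.catalysts_present
    npp, np_, nt, ap, am, memb = _chem_step_arrays(
        rng, params,
        one(pools.npp), one(pools.np_), pools.nt[None, :].astype(np.int64),
        one(pools.ap), one(pools.am_free), one(pools.am_membrane),
        mask(context.inside_protocell),
        mask("Npsr" in cats), mask("Nsr" in cats), mask("Asr" in cats),
    )
    return RoomPools(
        npp=int(npp[0]), np_=int(np_[0]), nt=nt[0].copy(),
        ap=int(ap[0]), am_free=int(am[0]), am_membrane=int(memb[0]),
    )


def room_catalysts(world: WorldState, room: int) -> frozenset[str]:
    """Active ribozyme roles present in a room's compartment.

    Imported lazily from the RNA layer to avoid a module cycle.
    """
    from .rna import active_ribozyme_roles

    roles: set[str] = set()
    for mol in world.rna[room]:
        roles |= active_ribozyme_roles(mol, world.design)
    return frozenset(roles)


def chemistry_phase(world: WorldState) -> None:
    """Run one vectorised chemistry step over every room of the world."""
    R = world.R
    npsr = np.zeros(R, dtype=bool)
    nsr = np.zeros(R, dtype=bool)
    asr = np.zeros(R, dtype=bool)
    from .rna import active_ribozyme_roles

    for room in range(R):
        if not world.rna[room]:
            continue
        roles: set[str] = set()
        for mol in world.rna[room]:
            roles |= active_ribozyme_roles(mol, world.design)
        if "Npsr" in roles:
            npsr[room] = True
        if "Nsr" in roles:
            nsr[room] = True
        if "Asr" in roles:
            asr[room] = True

    (world.npp, world.np_, world.nt, world.ap, world.am, world.memb) = \
        _chem_step_arrays(
            world.rng, world.params,
            world.npp, world.np_, world.nt, world.ap, world.am, world.memb,
            world.occupied, npsr, nsr, asr,
        )
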