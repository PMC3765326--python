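"""Membrane assembly, permeation, protocell division/fusion/breakage and the
movement phase.

A protocell is a room whose molecule pools are enclosed by a bilayer of
``b`` amphiphiles.  ``b/2`` stands in for the membrane surface area and
``(b/2)**(3/2)`` for the enclosed volume, so ``n / (b/2)**(3/2)`` -- with
``n`` the count of impermeable units inside (free nucleotides plus RNA
residues) -- is the interior "ion concentration".  That concentration
damps amphiphile loss (osmotic swelling, factor ``F_OP``) and damps the
influx of charged precursors (Donnan equilibrium, factor ``F_DE``);
uncharged amphiphile precursors feel no Donnan damping.
"""

from __future__ import annotations

import numpy as np

from .core import ParameterSet, RNAMolecule, WorldState

__all__ = [
    "membrane_formation_probability",
    "amphiphile_leave_probability",
    "permeation_in_probability",
    "division_probability",
    "protocell_phase",
    "movement_phase",
]

#: Permeable species and their base permeation probabilities' field names.
PERMEABLE = {"Np": "P_NPP", "Npp": "P_NPPP", "Ap": "P_APP"}
#: Donnan damping applies to the charged species only.
DONNAN_APPLIES = {"Np": True, "Npp": True, "Ap": False}


def membrane_formation_probability(a: int, params: ParameterSet) -> float:
    """``1 - (1 - P_MF) ** (a - L_AM + 1)`` for ``a >= L_AM`` amphiphiles
    in a room, else 0: more amphiphiles, more chances to close a bilayer."""
    x = a - params.L_AM + 1
    if x < 1:
        return 0.0
    return 1.0 - (1.0 - params.P_MF) ** x


def _concentration(n: int, b: int) -> float:
    return n / (b / 2.0) ** 1.5


def amphiphile_leave_probability(b: int, n: int, params: ParameterSet) -> float:
    """``P_ALM`` damped by osmotic swelling:
    ``P_ALM / (1 + F_OP * n / (b/2)**(3/2))``."""
    if b <= 0:
        raise ValueError("a protocell membrane has b > 0 amphiphiles")
    return params.P_ALM / (1.0 + params.F_OP * _concentration(n, b))


def permeation_in_probability(species: str, b: int, n: int,
                              params: ParameterSet) -> float:
    """Inward permeation probability for one molecule of ``species``
    sitting next to a protocell of membrane size ``b`` and interior
    impermeable content ``n``.

    ``y = (b / L_AM) ** (3/2)`` scales the base probability with the
    cellular space; charged species are additionally damped by the Donnan
    factor.
    """
    if species not in PERMEABLE:
        raise ValueError(f"species {species!r} does not permeate")
    y = (b / params.L_AM) ** 1.5
    base = getattr(params, PERMEABLE[species])
    p = 1.0 - (1.0 - base) ** y
    if DONNAN_APPLIES[species]:
        p = p / (1.0 + params.F_DE * _concentration(n, b))
    return min(p, 1.0)


def division_probability(b: int, params: ParameterSet) -> float:
    """``max(0, P_CD * (1 - 2 * L_AM / b))``: only a protocell holding more
    than twice the assembly limit of amphiphiles can divide."""
    if b <= 0:
        return 0.0
    return max(0.0, params.P_CD * (1.0 - 2.0 * params.L_AM / b))


# --------------------------------------------------------------------------
# Displacement helpers ("push away")
# --------------------------------------------------------------------------

def _free_neighbor_rooms(world: WorldState, room: int,
                         exclude: int | None = None) -> list[int]:
    out = []
    for nb in world.neighbor_idx[room]:
        nb = int(nb)
        if nb != exclude and not world.occupied[nb]:
            out.append(nb)
    return out


def _displace_contents(world: WorldState, room: int, targets: list[int]) -> None:
    """Scatter every free molecule of ``room`` uniformly over ``targets``."""
    rng = world.rng
    k = len(targets)
    for arr in (world.npp, world.np_, world.ap, world.am):
        n = int(arr[room])
        if n:
            dest = rng.integers(0, k, size=n)
            arr[room] = 0
            for t, cnt in zip(*np.unique(dest, return_counts=True)):
                arr[targets[int(t)]] += int(cnt)
    for base in range(4):
        n = int(world.nt[room, base])
        if n:
            dest = rng.integers(0, k, size=n)
            world.nt[room, base] = 0
            for t, cnt in zip(*np.unique(dest, return_counts=True)):
                world.nt[targets[int(t)], base] += int(cnt)
    if world.rna[room]:
        for mol in world.rna[room]:
            world.rna[targets[int(rng.integers(0, k))]].append(mol)
        world.rna[room] = []


def _move_all_contents(world: WorldState, src: int, dst: int) -> None:
    for arr in (world.npp, world.np_, world.ap, world.am, world.memb):
        arr[dst] += arr[src]
        arr[src] = 0
    world.nt[dst] += world.nt[src]
    world.nt[src] = 0
    world.rna[dst].extend(world.rna[src])
    world.rna[src] = []


# --------------------------------------------------------------------------
# Protocell phase
# --------------------------------------------------------------------------

def _try_form_membranes(world: WorldState) -> None:
    params = world.params
    rng = world.rng
    candidates = np.nonzero((~world.occupied) & (world.am >= params.L_AM))[0]
    for room in candidates:
        room = int(room)
        a = int(world.am[room])
        if rng.random() < membrane_formation_probability(a, params):
            world.memb[room] = a
            world.am[room] = 0
            world.occupied[room] = True


def _divide(world: WorldState, room: int) -> None:
    rng = world.rng
    targets = _free_neighbor_rooms(world, room)
    if not targets:
        return
    target = targets[int(rng.integers(0, len(targets)))]
    spill = _free_neighbor_rooms(world, target)
    if not spill:
        return
    _displace_contents(world, target, spill)

    # binomial halving of membrane and every interior pool
    b_off = int(rng.binomial(int(world.memb[room]), 0.5))
    world.memb[room] -= b_off
    world.memb[target] = b_off
    for arr in (world.npp, world.np_, world.ap, world.am):
        k = int(rng.binomial(int(arr[room]), 0.5))
        arr[room] -= k
        arr[target] += k
    for base in range(4):
        k = int(rng.binomial(int(world.nt[room, base]), 0.5))
        world.nt[room, base] -= k
        world.nt[target, base] += k
    stay: list[RNAMolecule] = []
    for mol in world.rna[room]:
        if rng.random() < 0.5:
            world.rna[target].append(mol)
        else:
            stay.append(mol)
    world.rna[room] = stay
    world.occupied[target] = True


def protocell_phase(world: WorldState) -> None:
    """Membrane and whole-cell events for one step.

    Pass order: membrane formation; then per protocell (randomised order)
    amphiphile join/leave, permeation in/out, division; then fusion of
    adjacent pairs; then breakage.
    """
    params = world.params
    rng = world.rng

    _try_form_membranes(world)

    cells = np.nonzero(world.occupied)[0]
    if cells.size == 0:
        return
    for room in rng.permutation(cells):
        room = int(room)
        if not world.occupied[room]:   # may have fused away
            continue
        b = int(world.memb[room])
        if b <= 0:
            # membrane fully decayed: the cell ceases to exist
            world.occupied[room] = False
            continue

        # amphiphile exchange with the membrane
        join = rng.binomial(int(world.am[room]), min(params.P_AJM, 1.0))
        world.am[room] -= join
        world.memb[room] += join
        n = world.impermeable_count(room)
        leave = rng.binomial(int(world.memb[room]),
                             amphiphile_leave_probability(
                                 int(world.memb[room]), n, params))
        world.memb[room] -= leave
        world.am[room] += leave
        b = int(world.memb[room])
        if b <= 0:
            world.occupied[room] = False
            continue

        # permeation: inward from adjacent naked rooms, outward to them
        naked = _free_neighbor_rooms(world, room)
        if naked:
            for species, arr in (("Np", world.np_), ("Npp", world.npp),
                                 ("Ap", world.ap)):
                p_in = permeation_in_probability(species, b, n, params)
                for nb in naked:
                    k = rng.binomial(int(arr[nb]), p_in)
                    arr[nb] -= k
                    arr[room] += k
                p_out = min(getattr(params, PERMEABLE[species]), 1.0)
                k = rng.binomial(int(arr[room]), p_out)
                if k:
                    arr[room] -= k
                    dest = rng.integers(0, len(naked), size=k)
                    for t, cnt in zip(*np.unique(dest, return_counts=True)):
                        arr[naked[int(t)]] += int(cnt)

        if rng.random() < division_probability(int(world.memb[room]), params):
            _divide(world, room)

    # fusion of adjacent pairs
    cells = np.nonzero(world.occupied)[0]
    for room in rng.permutation(cells):
        room = int(room)
        if not world.occupied[room]:
            continue
        for nb in world.neighbor_idx[room]:
            nb = int(nb)
            if nb <= room or not world.occupied[nb]:
                continue
            if rng.random() < params.P_CF:
                keep, gone = (room, nb) if rng.random() < 0.5 else (nb, room)
                _move_all_contents(world, gone, keep)
                world.occupied[gone] = False
                break

    # breakage
    cells = np.nonzero(world.occupied)[0]
    for room in cells:
        room = int(room)
        if rng.random() < params.P_CB:
            world.am[room] += world.memb[room]
            world.memb[room] = 0
            world.occupied[room] = False


# --------------------------------------------------------------------------
# Movement phase
# --------------------------------------------------------------------------

def _move_species(world: WorldState, arr: np.ndarray, p: float,
                  naked: np.ndarray) -> None:
    """Vectorised movement of one count-pool species.

    Each molecule in a naked room moves with probability ``p`` to a
    uniformly chosen neighbour; a move into an occupied room is aborted
    (membranes cannot be crossed by diffusion).
    """
    rng = world.rng
    movers = rng.binomial(arr * naked, min(p, 1.0))
    if not movers.any():
        return
    arr -= movers
    remaining = movers.copy()
    for d in range(4):
        share = 1.0 / (4 - d)
        going = rng.binomial(remaining, share) if d < 3 else remaining
        remaining = remaining - going
        dest = world.neighbor_idx[:, d]
        blocked = world.occupied[dest]
        # blocked movers stay where they are
        arr += np.where(blocked, going, 0)
        np.add.at(arr, dest, np.where(blocked, 0, going))


def movement_phase(world: WorldState) -> None:
    """Diffusion of free molecules and whole protocells between rooms.

    Small molecules move with ``P_MV``; a free RNA of mass ``m`` with
    ``P_MV / m**(1/3)``; a protocell with ``P_MC``, pushing the free
    molecules of the room it enters out into that room's other
    protocell-free neighbours (the move aborts if it cannot).
    """
    params = world.params
    rng = world.rng
    naked = ~world.occupied

    for arr in (world.npp, world.np_, world.ap, world.am):
        _move_species(world, arr, params.P_MV, naked)
    for base in range(4):
        col = world.nt[:, base].copy()
        _move_species(world, col, params.P_MV, naked)
        world.nt[:, base] = col

    # free RNA molecules
    rna_rooms = [room for room in range(world.R)
                 if world.rna[room] and not world.occupied[room]]
    for room in rna_rooms:
        stay: list[RNAMolecule] = []
        for mol in world.rna[room]:
            p = params.P_MV / mol.mass ** (1.0 / 3.0)
            if rng.random() < p:
                dest = int(world.neighbor_idx[room, rng.integers(0, 4)])
                if not world.occupied[dest]:
                    world.rna[dest].append(mol)
                    continue
            stay.append(mol)
        world.rna[room] = stay

    # protocells
    cells = np.nonzero(world.occupied)[0]
    for room in rng.permutation(cells):
        room = int(room)
        if not world.occupied[room] or rng.random() >= params.P_MC:
            continue
        dest = int(world.neighbor_idx[room, rng.integers(0, 4)])
        if world.occupied[dest]:
            continue
        spill = _free_neighbor_rooms(world, dest, exclude=room)
        if not spill:
            continue
        _displace_contents(world, dest, spill)
        _move_all_contents(world, room, dest)
        world.occupied[room] = False
        world.occupied[dest] = True
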