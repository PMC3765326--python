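"""Per-step orchestration, inoculation, census and experiment harness.

A run proceeds step by step: small-molecule chemistry everywhere, RNA
events room by room (in randomised order), protocell events, then the
movement phase.  The harness layers on top of that the inoculation
schedule (empty protocells early, gene-carrying and control protocells
later), periodic censuses, the spread criterion, replicate batches over
seed lists and one-parameter sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemistry import chemistry_phase
from .core import (
    GenomeDesign,
    ParameterSet,
    RNAMolecule,
    WorldState,
    init_world,
)
from .membrane import movement_phase, protocell_phase
from .rna import canonical_rotation, rna_phase

__all__ = [
    "InoculationEvent",
    "ScheduleError",
    "CensusRecord",
    "SpreadCriterion",
    "ExperimentConfig",
    "step",
    "inoculate",
    "census",
    "classify_spread",
    "run_case",
    "run_batch",
    "run_sweep",
    "default_schedule",
    "full_config",
    "scaled_config",
]


class ScheduleError(RuntimeError):
    """An inoculation could not be applied as scheduled."""


@dataclass(frozen=True)
class InoculationEvent:
    """One scheduled protocell inoculation.

    ``kind`` is ``"empty"`` (membrane only) or ``"seeded"``; a seeded cell
    receives ``ribozyme_copies`` of each of the four ribozymes plus
    ``chromosome_copies`` of the chromosome arm named by ``genome``
    (``"sense"``/``"antisense"``) or of the ``"control"`` circle.
    """

    step: int
    coord: tuple[int, int]
    kind: str = "seeded"
    genome: str = "sense"
    ribozyme_copies: int = 5
    chromosome_copies: int = 5

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("inoculation steps are strictly positive")
        if self.kind not in ("empty", "seeded"):
            raise ValueError(f"unknown inoculation kind {self.kind!r}")
        if self.genome not in ("sense", "antisense", "control"):
            raise ValueError(f"unknown genome arm {self.genome!r}")


@dataclass
class CensusRecord:
    """Counts of the tracked species at one sampled step."""

    step: int
    sense: int = 0
    antisense: int = 0
    control: int = 0
    rep: int = 0
    nsr: int = 0
    npsr: int = 0
    asr: int = 0
    npp: int = 0
    np_: int = 0
    nt: int = 0
    ap: int = 0
    am: int = 0
    protocells: int = 0
    chromosome_cells: int = 0
    length_hist: dict[int, int] = field(default_factory=dict)

    FIELDS = ("step", "sense", "antisense", "control", "rep", "nsr", "npsr",
              "asr", "npp", "np_", "nt", "ap", "am", "protocells",
              "chromosome_cells")

    def as_row(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


@dataclass(frozen=True)
class SpreadCriterion:
    """Spread = the sense-chain count holds at or above ``threshold`` for
    every sample in the final ``window`` fraction of the series."""

    threshold: int = 50
    window: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold >= 1")
        if not (0.0 < self.window <= 1.0):
            raise ValueError("window in (0, 1]")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulation case."""

    params: ParameterSet = field(default_factory=ParameterSet)
    design: GenomeDesign = field(default_factory=GenomeDesign)
    seed: int = 1
    steps: int = 200_000
    sample_interval: int = 1000
    chromosome_topology: str = "circular"   # "circular" | "linear"
    genome_arm: str = "sense"               # arm seeded in chromosome cells
    schedule: list[InoculationEvent] = field(default_factory=list)
    criterion: SpreadCriterion = field(default_factory=SpreadCriterion)

    def with_overrides(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# One step
# --------------------------------------------------------------------------

def step(world: WorldState) -> WorldState:
    """Advance the world by one full time step.

    Order: chemistry everywhere (vectorised); RNA events room by room in a
    freshly randomised room order; protocell events; movement; counter.
    The random-ligation event counts for all rooms are pre-drawn in one
    vectorised pass so that rooms holding nothing but small molecules are
    not visited individually.
    """
    params = world.params
    rng = world.rng

    chemistry_phase(world)

    # pair counts for spontaneous ligation, all rooms at once
    n_free = np.zeros(world.R, dtype=np.int64)
    rna_rooms = []
    for room in range(world.R):
        mols = world.rna[room]
        if mols:
            rna_rooms.append(room)
            n_free[room] = sum(
                1 for m in mols
                if not m.circular and not m.is_template and not m.rep_bound
            )
    k = world.nt.sum(axis=1) + n_free
    n_pairs = k * (k - 1) // 2
    lig_events = rng.binomial(n_pairs, min(params.P_RL, 1.0))

    visit = sorted(set(rna_rooms) | set(np.nonzero(lig_events)[0].tolist()))
    if visit:
        order = rng.permutation(len(visit))
        for i in order:
            room = visit[int(i)]
            rna_phase(world, room, int(lig_events[room]))

    protocell_phase(world)
    movement_phase(world)
    world.step_count += 1
    return world


# --------------------------------------------------------------------------
# Inoculation
# --------------------------------------------------------------------------

def _nearest_free_room(world: WorldState, room: int) -> int:
    if not world.occupied[room]:
        return room
    # breadth-first ring search on the torus
    seen = {room}
    frontier = [room]
    while frontier:
        nxt = []
        for r in frontier:
            for nb in world.neighbor_idx[r]:
                nb = int(nb)
                if nb in seen:
                    continue
                if not world.occupied[nb]:
                    return nb
                seen.add(nb)
                nxt.append(nb)
        frontier = nxt
    raise ScheduleError("no protocell-free room available")


def inoculate(world: WorldState, event: InoculationEvent,
              topology: str = "circular",
              on_occupied: str = "error") -> None:
    """Insert one protocell (membrane of exactly ``L_AM`` amphiphiles) at
    the scheduled room; this is the only operation that adds mass.

    ``on_occupied`` selects the policy when the target room already holds a
    protocell: ``"error"`` raises :class:`ScheduleError` (the contract for
    hand-written schedules); ``"nearest_free"`` walks outward to the
    closest free room (used by the experiment runner, where cells grown
    from earlier inoculations may have drifted onto the target).
    """
    room = world.room_index(event.coord)
    if world.occupied[room]:
        if on_occupied == "nearest_free":
            room = _nearest_free_room(world, room)
        else:
            raise ScheduleError(
                f"room {event.coord} is occupied at step {world.step_count}"
            )
    world.memb[room] = world.params.L_AM
    world.occupied[room] = True
    if event.kind == "empty":
        return

    design = world.design
    circular = topology == "circular"
    if event.genome == "sense":
        chrom_seq = design.sense_sequence
    elif event.genome == "antisense":
        chrom_seq = design.antisense_sequence
    else:
        chrom_seq = design.control_sequence
    for domain in design.domains.values():
        for _ in range(event.ribozyme_copies):
            world.rna[room].append(RNAMolecule(seq=domain))
    for _ in range(event.chromosome_copies):
        world.rna[room].append(RNAMolecule(seq=chrom_seq, circular=circular))


# --------------------------------------------------------------------------
# Census
# --------------------------------------------------------------------------

def _census_identity(seq: str, circular: bool, design: GenomeDesign,
                     linear_chromosome_mode: bool) -> str | None:
    """Sequence identity of one chain for counting purposes.

    Unlike catalytic activity, identity ignores the transient folding
    state: a Rep currently working a template is still counted as a Rep.
    """
    if circular or (linear_chromosome_mode and len(seq) == len(design.sense_sequence)):
        canon = canonical_rotation(seq)
        if canon == canonical_rotation(design.sense_sequence):
            return "sense"
        if canon == canonical_rotation(design.antisense_sequence):
            return "antisense"
        if canon == canonical_rotation(design.control_sequence):
            return "control"
    if not circular:
        for role, domain in design.domains.items():
            if len(seq) < 1.5 * len(domain) and domain in seq:
                return role.lower()
    return None


def census(world: WorldState) -> CensusRecord:
    """Count every tracked species and bin the chain-length distribution.

    The histogram includes the monomers (free nucleotides) at length 1 and
    nascent duplex fragments at their current length, so its total mass
    equals the nucleotide plus RNA-residue content of the world.
    """
    design = world.design
    rec = CensusRecord(
        step=world.step_count,
        npp=int(world.npp.sum()),
        np_=int(world.np_.sum()),
        nt=int(world.nt.sum()),
        ap=int(world.ap.sum()),
        am=int(world.am.sum()),
        protocells=int(world.occupied.sum()),
    )
    hist: dict[int, int] = {}
    if rec.nt:
        hist[1] = rec.nt
    linear_mode = world.linear_chromosome_mode

    def tally(mol: RNAMolecule) -> str | None:
        hist[len(mol.seq)] = hist.get(len(mol.seq), 0) + 1
        for seg in mol.segments:
            hist[seg.r] = hist.get(seg.r, 0) + 1
        ident = _census_identity(mol.seq, mol.circular, design, linear_mode)
        if ident == "sense":
            rec.sense += 1
        elif ident == "antisense":
            rec.antisense += 1
        elif ident == "control":
            rec.control += 1
        elif ident == "rep":
            rec.rep += 1
        elif ident == "nsr":
            rec.nsr += 1
        elif ident == "npsr":
            rec.npsr += 1
        elif ident == "asr":
            rec.asr += 1
        return ident

    for room in range(world.R):
        has_sense = False
        for mol in world.rna[room]:
            ident = tally(mol)
            has_sense = has_sense or ident == "sense"
            if mol.bound_rep is not None:
                ident = tally(mol.bound_rep)
                has_sense = has_sense or ident == "sense"
        if has_sense and world.occupied[room]:
            rec.chromosome_cells += 1
    rec.length_hist = dict(sorted(hist.items()))
    return rec


def classify_spread(series: list[CensusRecord],
                    criterion: SpreadCriterion,
                    species: str = "sense") -> bool:
    """True iff the tracked count stays at or above the threshold over the
    final window of the sampled series."""
    if not series:
        raise ValueError("empty census series")
    n_tail = max(1, math.ceil(len(series) * criterion.window))
    return all(getattr(rec, species) >= criterion.threshold
               for rec in series[-n_tail:])


# --------------------------------------------------------------------------
# Harness
# --------------------------------------------------------------------------

@dataclass
class CaseResult:
    config: ExperimentConfig
    series: list[CensusRecord]
    world: WorldState

    @property
    def final(self) -> CensusRecord:
        return self.series[-1]

    def spread(self, species: str = "sense") -> bool:
        return classify_spread(self.series, self.config.criterion, species)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([rec.as_row() for rec in self.series])


def run_case(config: ExperimentConfig, *,
             on_occupied: str = "nearest_free") -> CaseResult:
    """Run one complete simulation case and sample its census series."""
    world = init_world(config.params, config.design, config.seed)
    world.linear_chromosome_mode = config.chromosome_topology == "linear"
    pending = sorted(config.schedule, key=lambda e: e.step)
    series = [census(world)]
    for _ in range(config.steps):
        while pending and pending[0].step == world.step_count:
            inoculate(world, pending.pop(0),
                      topology=config.chromosome_topology,
                      on_occupied=on_occupied)
        step(world)
        if world.step_count % config.sample_interval == 0 \
                or world.step_count == config.steps:
            series.append(census(world))
    return CaseResult(config=config, series=series, world=world)


def run_batch(config: ExperimentConfig, seeds: list[int]) -> pd.DataFrame:
    """One row per seed: the final census plus the spread classification."""
    rows = []
    for seed in seeds:
        result = run_case(config.with_overrides(seed=seed))
        row = result.final.as_row()
        row["seed"] = seed
        row["spread"] = result.spread()
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")


def run_sweep(config: ExperimentConfig, parameter: str, values: list,
              seeds: list[int]) -> pd.DataFrame:
    """Mean final counts of chromosome, ribozymes and control for each value
    of one parameter, averaged over the seed list.

    ``parameter`` is either a parameter symbol (e.g. ``"F_IB"``) or
    ``"chromosome_topology"``.
    """
    rows = []
    for value in values:
        if parameter == "chromosome_topology":
            cfg = config.with_overrides(chromosome_topology=value)
        else:
            cfg = config.with_overrides(
                params=config.params.replace(**{parameter: value})
            )
        batch = run_batch(cfg, seeds)
        row = {
            "value": value,
            "sense": batch["sense"].mean(),
            "rep": batch["rep"].mean(),
            "nsr": batch["nsr"].mean(),
            "npsr": batch["npsr"].mean(),
            "asr": batch["asr"].mean(),
            "control": batch["control"].mean(),
            "spread_fraction": batch["spread"].mean(),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("value")


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

def default_schedule(params: ParameterSet, *,
                     n_empty: int = 10,
                     n_chromosome: int = 10,
                     n_control: int = 10,
                     empty_step: int = 1000,
                     seeded_step: int = 10_000,
                     genome_arm: str = "sense",
                     ribozyme_copies: int = 5,
                     chromosome_copies: int = 5) -> list[InoculationEvent]:
    """The reference inoculation design.

    Empty protocells appear early on the anti-diagonal; later, protocells
    carrying the four ribozymes plus the chromosome, and matching cells
    carrying the control instead, are placed at alternating evenly spaced
    rooms along the main diagonal.
    """
    N = params.N
    events: list[InoculationEvent] = []
    for j in range(n_empty):
        i = (j * N) // max(n_empty, 1)
        events.append(InoculationEvent(step=empty_step,
                                       coord=(i, (N - 1 - i) % N),
                                       kind="empty"))
    n_seeded = n_chromosome + n_control
    for j in range(n_seeded):
        i = (j * N) // max(n_seeded, 1)
        genome = genome_arm if j % 2 == 0 else "control"
        if n_control == 0:
            genome = genome_arm
        elif n_chromosome == 0:
            genome = "control"
        events.append(InoculationEvent(
            step=seeded_step, coord=(i, i), genome=genome,
            ribozyme_copies=ribozyme_copies,
            chromosome_copies=chromosome_copies,
        ))
    return events


def full_config(seed: int = 1, steps: int = 200_000) -> ExperimentConfig:
    """The reference system: 40 x 40 grid, 8e4 Npp, 6e4 Ap, inoculation of
    10 empty cells at step 1e3 and 10 + 10 seeded cells at step 1e4."""
    params = ParameterSet()
    return ExperimentConfig(
        params=params,
        seed=seed,
        steps=steps,
        sample_interval=1000,
        schedule=default_schedule(params),
        criterion=SpreadCriterion(threshold=50, window=0.1),
    )


def scaled_config(seed: int = 1, steps: int = 20_000) -> ExperimentConfig:
    """A tenfold-reduced preset for fast experimentation and testing.

    Extensive quantities are scaled by ~10 relative to the reference
    system (grid area 1600 -> 169 rooms, feedstock 8e4 -> 8e3 and
    6e4 -> 6e3, step budget 2e5 -> 2e4, seeded cells 10+10 -> 3+3)
    while intensive ones are kept:
    per-room molecule density (~50 Npp per room), the membrane size
    ``L_AM`` (and with it the osmotic/Donnan concentration scale), and the
    fraction of rooms a full protocell population can cover
    (T_APB / L_AM = 10 cells on 169 rooms ~ 100 on 1600).  The spread
    threshold is twice the seeded chromosome copy number (2 x 15 = 30):
    the population must at least double over its inoculum and hold that
    level.

    Inoculation steps are scaled less aggressively than the step budget
    (empties at 500, gene-carrying cells at 3000) because the chemical
    relaxation of the feedstock -- the non-enzymatic build-up of interior
    monomer stocks that replication feeds on -- runs on per-molecule
    timescales (~1/P_NF steps) that do not shrink with system size.
    """
    params = ParameterSet().replace(N=13, T_NPPB=8000, T_APB=6000)
    return ExperimentConfig(
        params=params,
        seed=seed,
        steps=steps,
        sample_interval=100,
        schedule=default_schedule(
            params, n_empty=3, n_chromosome=3, n_control=3,
            empty_step=500, seeded_step=3000,
        ),
        criterion=SpreadCriterion(threshold=30, window=0.1),
    )
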