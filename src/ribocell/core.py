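"""Domain types, parameter validation, world construction and conservation audits.

The simulated world is an ``N x N`` toroidal grid of "rooms".  A room holds
either a free pool of molecules or exactly one membrane-bounded protocell
(in which case the room's pools are the protocell interior).  Molecule
species tracked as per-room integer counts:

* ``Npp`` -- nucleotide precursor's precursor (the raw feedstock),
* ``Np``  -- nucleotide precursor,
* ``Nt``  -- free nucleotides, by base (A, U, G, C),
* ``Ap``  -- amphiphile precursor,
* ``Am``  -- free amphiphiles,

plus, per occupied room, the number of amphiphiles in the membrane.
RNA chains of length >= 2 are individual :class:`RNAMolecule` objects;
a 1-mer is a free nucleotide and lives in the ``Nt`` pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from functools import cached_property
from typing import Iterator

import numpy as np

__all__ = [
    "BASES",
    "BASE_INDEX",
    "ParameterSet",
    "ValidationReport",
    "validate_params",
    "GenomeDesign",
    "Segment",
    "RNAMolecule",
    "WorldState",
    "neighbors",
    "init_world",
    "nucleotide_mass_audit",
    "amphiphile_mass_audit",
]

#: Fixed base alphabet and the index used for the per-room nucleotide pools.
BASES = "AUGC"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Every per-step probability, factor and size limit of the model.

    All ``P_*`` values are dimensionless per-step probabilities; ``F_*``
    values are dimensionless multipliers; ``L_AM``, ``N`` and ``T_*`` are
    integer sizes/counts.  Defaults are the reference parameterisation under
    which the circular chromosome spreads.
    """

    # -- chemistry of small molecules -------------------------------------
    P_NPF: float = 5e-4    #: Npp -> Np, uncatalysed
    P_NPFR: float = 0.9    #: Npp -> Np, catalysed by Npsr
    P_NF: float = 5e-4     #: Np -> nucleotide, uncatalysed
    P_NFR: float = 0.9     #: Np -> nucleotide, catalysed by Nsr
    P_ND: float = 5e-4     #: nucleotide -> Np (decay)
    P_NDE: float = 2e-5    #: terminal RNA residue -> Np (end decay)
    P_NPD: float = 5e-4    #: Np -> Npp (decay)
    P_AF: float = 5e-4     #: Ap -> Am, uncatalysed
    P_AFR: float = 0.9     #: Ap -> Am, catalysed by Asr
    P_AD: float = 5e-4     #: free Am -> Ap (decay)
    P_ADM: float = 5e-5    #: membrane Am -> Ap (decay within membrane)

    # -- RNA chain events --------------------------------------------------
    P_RL: float = 1e-7     #: random end-to-end ligation of two chains
    P_EL: float = 1e-7     #: end-to-end self-ligation (cyclization)
    P_BB: float = 2e-6     #: phosphodiester bond breaking
    P_LRTT: float = 0.01   #: linear RNA turning into a template (unfolding)
    P_CRTT: float = 0.9    #: circular RNA turning into a template
    P_AT: float = 0.2      #: template attracting a nucleotide/oligomer
    P_FP: float = 0.01     #: false base pair tolerated per residue
    P_TL: float = 5e-4     #: template-directed ligation, uncatalysed
    P_TLR: float = 0.9     #: template-directed ligation, catalysed by Rep
    P_FLR: float = 0.01    #: Rep ligation across a false flanking pair
    P_RB: float = 0.9      #: Rep binding onto a template
    P_RD: float = 0.9      #: Rep dropping from a template
    P_SP: float = 0.5      #: separation of a single base pair

    # -- membranes and protocells -----------------------------------------
    P_MF: float = 0.1      #: membrane forming (at a = L_AM)
    P_CB: float = 1e-5     #: protocell breaking
    P_CD: float = 0.02     #: protocell dividing (at large b)
    P_CF: float = 5e-4     #: two adjacent protocells fusing
    P_AJM: float = 0.9     #: free amphiphile joining a membrane
    P_ALM: float = 5e-5    #: membrane amphiphile leaving (before osmotic damping)
    P_NPP: float = 0.01    #: Np permeating the membrane
    P_NPPP: float = 0.2    #: Npp permeating the membrane
    P_APP: float = 0.05    #: Ap permeating the membrane

    # -- movement ----------------------------------------------------------
    P_MV: float = 0.5      #: movement of a small molecule (RNA: P_MV / m^(1/3))
    P_MC: float = 0.05     #: movement of a protocell

    # -- factors -----------------------------------------------------------
    F_DE: float = 5.0      #: Donnan-equilibrium damping of inward permeation
    F_DO: float = 20.0     #: degradation speed-up outside protocells
    F_IB: float = 100.0    #: breaking speed-up at inter-gene (U|G) sites
    F_OP: float = 5.0      #: osmotic damping of amphiphile loss

    # -- sizes -------------------------------------------------------------
    L_AM: int = 600        #: lower limit of amphiphiles to form a membrane
    N: int = 40            #: grid side length
    T_APB: int = 60_000    #: total amphiphile precursors introduced at step 0
    T_NPPB: int = 80_000   #: total nucleotide precursors' precursors at step 0

    def replace(self, **overrides) -> "ParameterSet":
        """Return a copy with the given symbols overridden."""
        return replace(self, **overrides)

    def probability_fields(self) -> Iterator[str]:
        return (f.name for f in fields(self) if f.name.startswith("P_"))


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


#: Orderings the probabilities are expected to obey: a violated ordering is
#: reported as a warning, not an error (such a parameter set is unusual but
#: still simulable).  Each entry reads "left should exceed right".
_EXPECTED_ORDERINGS = [
    ("P_TLR", "P_TL"),
    ("P_NPFR", "P_NPF"),
    ("P_NFR", "P_NF"),
    ("P_AFR", "P_AF"),
    ("P_TL", "P_RL"),
    ("P_ND", "P_NDE"),
    ("P_AD", "P_ADM"),
    ("P_MF", "P_CB"),
    ("P_AJM", "P_ALM"),
    ("P_MV", "P_MC"),
    ("P_NPPP", "P_NPP"),
]


def validate_params(params: ParameterSet) -> ValidationReport:
    """Check ranges (errors) and the expected rate orderings (warnings).

    Out-of-range values -- a probability outside [0, 1], a non-positive
    factor or size -- are hard errors.  Orderings such as "the catalysed
    rate should exceed the uncatalysed one" produce warnings only.
    """
    report = ValidationReport()
    for name in params.probability_fields():
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            report.errors.append(f"{name} = {v!r} is not a probability in [0, 1]")
    for name, lower in (("F_IB", 1.0), ("F_DO", 1.0), ("F_DE", 0.0), ("F_OP", 0.0)):
        if not getattr(params, name) > lower:
            report.errors.append(f"{name} must be > {lower}")
    for name in ("L_AM", "N"):
        if getattr(params, name) < 1:
            report.errors.append(f"{name} must be >= 1")
    for name in ("T_APB", "T_NPPB"):
        if getattr(params, name) < 0:
            report.errors.append(f"{name} must be >= 0")
    if report.errors:
        return report
    for hi, lo in _EXPECTED_ORDERINGS:
        if not getattr(params, hi) > getattr(params, lo):
            report.warnings.append(
                f"expected {hi} > {lo}, got {getattr(params, hi)!r} <= {getattr(params, lo)!r}"
            )
    return report


# --------------------------------------------------------------------------
# Genome design
# --------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class GenomeDesign:
    """The four ribozyme gene domains, the chromosome built from them, and
    the functionless control sequence.

    The sense chain of the chromosome is the circular concatenation of the
    four domains in order Rep, Nsr, Npsr, Asr.  Every inter-domain junction,
    including the wrap-around one, is a U immediately followed by G -- the
    two-residue stand-in for an embedded self-cleaving ribozyme -- while no
    such U-G adjacency occurs inside any domain, so a full-length linear
    sense transcript cleaves into exactly the four gene products.
    """

    domain_Rep: str = "GAGUCUCU"
    domain_Nsr: str = "GCUCGUAU"
    domain_Npsr: str = "GGUUCGAU"
    domain_Asr: str = "GCGACUUU"
    control_sequence: str = "GCCUUAGUGGACUCUUGAUAGCGUGGAAGUCU"

    @cached_property
    def domains(self) -> dict[str, str]:
        return {
            "Rep": self.domain_Rep,
            "Nsr": self.domain_Nsr,
            "Npsr": self.domain_Npsr,
            "Asr": self.domain_Asr,
        }

    @cached_property
    def sense_sequence(self) -> str:
        return self.domain_Rep + self.domain_Nsr + self.domain_Npsr + self.domain_Asr

    @cached_property
    def antisense_sequence(self) -> str:
        return _revcomp(self.sense_sequence)

    def validate(self) -> None:
        """Raise ``ValueError`` on a malformed design."""
        seqs = list(self.domains.values()) + [self.control_sequence]
        for s in seqs:
            bad = set(s) - set(BASES)
            if bad:
                raise ValueError(f"invalid bases {sorted(bad)} in {s!r}")
        sense = self.sense_sequence
        doms = list(self.domains.values())
        for i, d in enumerate(doms):
            if "UG" in d:
                raise ValueError(f"self-cleavage label U-G inside domain {d!r}")
            nxt = doms[(i + 1) % len(doms)]
            if not (d.endswith("U") and nxt.startswith("G")):
                raise ValueError(f"junction after domain {d!r} is not U|G")
        if len(self.control_sequence) != len(sense):
            raise ValueError("control sequence length differs from the chromosome")
        doubled = self.control_sequence * 2
        for name, d in self.domains.items():
            if d in doubled:
                raise ValueError(f"control sequence contains the {name} domain")


# --------------------------------------------------------------------------
# RNA molecules
# --------------------------------------------------------------------------

@dataclass(eq=False)
class Segment:
    """A nascent product fragment base-paired onto a template.

    ``start`` is the template position (0-based; modular for circular
    templates) of the first paired residue.  ``bases`` holds the product
    residues in template coordinate order, so the free product strand read
    5'->3' is ``bases`` reversed.  ``mismatch`` flags non-Watson-Crick
    pairs.  ``closed`` marks a full-coverage copy of a circular template
    whose final nick has been ligated: it is released as a circular RNA.
    """

    start: int
    bases: str
    mismatch: tuple[bool, ...]

    closed: bool = False

    @property
    def r(self) -> int:
        """Number of base pairs in this duplex segment."""
        return len(self.bases)

    def positions(self, length: int) -> list[int]:
        return [(self.start + k) % length for k in range(self.r)]

    def product_sequence(self) -> str:
        """The product strand 5'->3'."""
        return self.bases[::-1]


@dataclass(eq=False)
class RNAMolecule:
    """A single RNA chain: its sequence, topology and replication state."""

    seq: str
    circular: bool = False
    is_template: bool = False
    rep_bound: bool = False
    segments: list[Segment] = field(default_factory=list)
    bound_rep: "RNAMolecule | None" = None
    # per-sequence caches, invalidated whenever ``seq`` is mutated in place
    _role_cache: frozenset | None = field(default=None, repr=False)
    _sites_cache: "list[int] | None" = field(default=None, repr=False)

    def invalidate_sequence_caches(self) -> None:
        self._role_cache = None
        self._sites_cache = None

    @property
    def mass(self) -> int:
        """Residue count of the chain itself (excluding aligned fragments)."""
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def total_residues(self) -> int:
        """Residues of the chain plus aligned fragments plus a bound Rep."""
        n = len(self.seq) + sum(s.r for s in self.segments)
        if self.bound_rep is not None:
            n += self.bound_rep.total_residues()
        return n

    def covered_positions(self) -> set[int]:
        length = len(self.seq)
        out: set[int] = set()
        for s in self.segments:
            out.update(s.positions(length))
        return out



# --------------------------------------------------------------------------
# World state
# --------------------------------------------------------------------------

def neighbors(coord: tuple[int, int], N: int) -> list[tuple[int, int]]:
    """The four von-Neumann neighbours of ``coord`` on the ``N x N`` torus.

    Order is fixed: up, down, left, right (with wrap-around).
    """
    r, c = coord
    if not (0 <= r < N and 0 <= c < N):
        raise ValueError(f"coordinate {coord!r} out of range for N = {N}")
    return [((r - 1) % N, c), ((r + 1) % N, c), (r, (c - 1) % N), (r, (c + 1) % N)]


class WorldState:
    """Complete state of the simulated grid.

    Per-room pools are flat numpy arrays indexed by ``room = row * N + col``;
    RNA molecules are per-room Python lists.  A single seeded generator
    (``rng``) drives every stochastic draw.
    """

    def __init__(self, params: ParameterSet, design: GenomeDesign, seed: int):
        report = validate_params(params)
        if not report.ok:
            raise ValueError("invalid parameters: " + "; ".join(report.errors))
        design.validate()
        self.params = params
        self.design = design
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.step_count = 0
        #: when True, full-length chromosome-sequence molecules are linear,
        #: exposed to end decay, but keep the chromosome's elevated
        #: template-conversion probability (the linear-chromosome control
        #: experiment).
        self.linear_chromosome_mode = False

        N = params.N
        self.N = N
        R = N * N
        self.R = R
        self.npp = np.zeros(R, dtype=np.int64)
        self.np_ = np.zeros(R, dtype=np.int64)
        self.nt = np.zeros((R, 4), dtype=np.int64)   # columns follow BASES
        self.ap = np.zeros(R, dtype=np.int64)
        self.am = np.zeros(R, dtype=np.int64)
        self.occupied = np.zeros(R, dtype=bool)
        self.memb = np.zeros(R, dtype=np.int64)
        self.rna: list[list[RNAMolecule]] = [[] for _ in range(R)]

        # Precomputed toroidal neighbour indices, order up/down/left/right.
        rows, cols = np.divmod(np.arange(R), N)
        self.neighbor_idx = np.stack(
            [
                ((rows - 1) % N) * N + cols,
                ((rows + 1) % N) * N + cols,
                rows * N + (cols - 1) % N,
                rows * N + (cols + 1) % N,
            ],
            axis=1,
        )

    # -- coordinates -------------------------------------------------------

    def room_index(self, coord: tuple[int, int]) -> int:
        r, c = coord
        if not (0 <= r < self.N and 0 <= c < self.N):
            raise ValueError(f"coordinate {coord!r} out of range")
        return r * self.N + c

    def coord_of(self, room: int) -> tuple[int, int]:
        return divmod(room, self.N)

    # -- derived per-room quantities ----------------------------------------

    def nt_total(self, room: int) -> int:
        return int(self.nt[room].sum())

    def rna_residues(self, room: int) -> int:
        return sum(m.total_residues() for m in self.rna[room])

    def impermeable_count(self, room: int) -> int:
        """n: free nucleotides plus all RNA residues in the room."""
        return self.nt_total(room) + self.rna_residues(room)

    # -- bookkeeping helpers -------------------------------------------------

    def add_nucleotide(self, room: int, base: str, k: int = 1) -> None:
        self.nt[room, BASE_INDEX[base]] += k

    def add_rna(self, room: int, mol: RNAMolecule) -> None:
        if len(mol.seq) == 1:
            # 1-mers are free nucleotides, governed by the nucleotide rates
            self.add_nucleotide(room, mol.seq)
        elif len(mol.seq) > 0:
            self.rna[room].append(mol)


def init_world(params: ParameterSet, design: GenomeDesign | None = None,
               seed: int = 0) -> WorldState:
    """Build a fresh world: raw materials scattered uniformly, no RNA,
    no protocells, step counter 0.

    ``T_NPPB`` nucleotide precursors' precursors and ``T_APB`` amphiphile
    precursors are placed independently and uniformly at random over the
    rooms (the spatial distribution of the initial feedstock is a model
    choice; uniform placement is the least structured one).
    """
    if design is None:
        design = GenomeDesign()
    world = WorldState(params, design, seed)
    rooms = world.rng.integers(0, world.R, size=params.T_NPPB)
    world.npp += np.bincount(rooms, minlength=world.R)
    rooms = world.rng.integers(0, world.R, size=params.T_APB)
    world.ap += np.bincount(rooms, minlength=world.R)
    return world


# --------------------------------------------------------------------------
# Conservation audits
# --------------------------------------------------------------------------

def nucleotide_mass_audit(world: WorldState) -> int:
    """Total nucleotide equivalents: Npp + Np + free nucleotides + every RNA
    residue (chains, aligned fragments and bound Reps alike)."""
    total = int(world.npp.sum() + world.np_.sum() + world.nt.sum())
    for room_mols in world.rna:
        for mol in room_mols:
            total += mol.total_residues()
    return total


def amphiphile_mass_audit(world: WorldState) -> int:
    """Total amphiphile equivalents: Ap + free Am + membrane Am."""
    return int(world.ap.sum() + world.am.sum() + world.memb.sum())
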