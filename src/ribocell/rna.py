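"""RNA-level events: degradation, ligation, cyclization and template-directed
replication.

Replication here is ligase-based assembly, not processive polymerisation: an
unfolded chain (the template) attracts complementary nucleotides and
oligomers one per step, adjacent aligned fragments are joined by
template-directed ligation (fast when a Rep replicase is bound), and duplex
regions fall apart with a probability that shrinks with their length.  A
copy assembled all the way around a circular template can be sealed by one
final ligation, releasing a circular complement -- this is how the circular
chromosome begets circular copies without rolling-circle synthesis.  Copies
released before completion are the linear "transcripts"; when they carry
U|G inter-gene sites (true of sense-orientation sequence only), the
breaking factor ``F_IB`` quickly resolves them into the individual gene
products.
"""

from __future__ import annotations

import functools
import math

import numpy as np

from .core import (
    BASES,
    BASE_INDEX,
    GenomeDesign,
    ParameterSet,
    RNAMolecule,
    Segment,
    WorldState,
)

__all__ = [
    "reverse_complement",
    "canonical_rotation",
    "active_ribozyme_roles",
    "cleavage_sites",
    "bond_breaking",
    "end_decay",
    "random_ligation_and_cyclization",
    "become_template",
    "attract_substrate",
    "attraction_phase",
    "template_ligation",
    "rep_binding",
    "dissociation",
    "dissociation_probability",
    "classify_molecule",
    "rna_phase",
]

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_COMPLEMENT_TABLE = str.maketrans("AUGC", "UACG")

#: Structural activity limit: an RNA acts as a ribozyme only if shorter than
#: 1.5 x its characteristic domain (extra residues disturb the fold).
ACTIVITY_LENGTH_FACTOR = 1.5


def reverse_complement(seq: str) -> str:
    """Reverse complement under Watson-Crick pairing A-U, G-C."""
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"invalid base {sorted(bad)[0]!r}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@functools.lru_cache(maxsize=65536)
def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation; identity key for circular RNA."""
    if not seq:
        return seq
    return min(seq[i:] + seq[:i] for i in range(len(seq)))


def active_ribozyme_roles(rna: RNAMolecule, design: GenomeDesign) -> set[str]:
    """Roles this molecule can currently catalyse.

    Activity requires a linear chain, free (folded) state, an embedded
    domain in sense orientation, and a chain shorter than 1.5 x the domain.
    Domains embedded in the circular chromosome are sterically silenced,
    and an unfolded (template-state) or Rep-engaged chain cannot act.
    """
    if rna.circular or rna.is_template or rna.rep_bound:
        return set()
    if rna._role_cache is None:
        n = len(rna.seq)
        roles = set()
        for role, domain in design.domains.items():
            ld = len(domain)
            if ld <= n < ACTIVITY_LENGTH_FACTOR * ld and domain in rna.seq:
                roles.add(role)
        rna._role_cache = frozenset(roles)
    return rna._role_cache


def cleavage_sites(rna: RNAMolecule) -> list[int]:
    """Bonds (0-based, bond ``i`` joins residues ``i`` and ``i+1``) that
    break more readily, i.e. whose 5' residue is U and 3' residue is G.

    Circular molecules return no sites: the embedded self-cleaving motif is
    sterically inactive in the closed circle.
    """
    if rna.circular:
        return []
    if rna._sites_cache is None:
        s = rna.seq
        rna._sites_cache = [i for i in range(len(s) - 1)
                            if s[i] == "U" and s[i + 1] == "G"]
    return rna._sites_cache


# --------------------------------------------------------------------------
# Degradation
# --------------------------------------------------------------------------

def _linearize(rna: RNAMolecule, open_bond: int) -> RNAMolecule:
    """Open a circular molecule at ``open_bond``; remap attached segments."""
    L = len(rna.seq)
    shift = (open_bond + 1) % L
    rna.seq = rna.seq[shift:] + rna.seq[:shift]
    rna.circular = False
    rna.invalidate_sequence_caches()
    for seg in rna.segments:
        seg.start = (seg.start - shift) % L
    return rna


def bond_breaking(
    rna: RNAMolecule,
    inside_protocell: bool,
    params: ParameterSet,
    rng: np.random.Generator,
) -> list[RNAMolecule]:
    """Break internal bonds independently; return the resulting molecules.

    Per-bond probability is ``P_BB``, multiplied by ``F_IB`` at a U|G
    self-cleavage site (linear chains only) and by ``F_DO`` outside a
    protocell, clamped to 1.  One break in a circle yields one linear
    chain of the same length; ``k`` breaks in a linear chain yield
    ``k + 1`` fragments.  Breaking disrupts a replication complex: any
    aligned fragments are released to the caller as products (kept in the
    returned molecules' place by the phase driver); a chain in template
    state loses that state along with its segments.
    """
    L = len(rna.seq)
    if L < 2:
        return [rna]
    outside_factor = 1.0 if inside_protocell else params.F_DO
    base_p = params.P_BB * outside_factor
    hot = cleavage_sites(rna)
    n_bonds = L if rna.circular else L - 1
    n_norm = n_bonds - len(hot)

    # Only two per-bond rates exist (plain and F_IB-boosted), so draw the
    # number of breaks of each kind first; the no-break case costs just two
    # binomial draws per molecule per step.
    k_norm = rng.binomial(n_norm, min(base_p, 1.0)) if n_norm > 0 else 0
    k_hot = (rng.binomial(len(hot), min(base_p * params.F_IB, 1.0))
             if hot else 0)
    if k_norm == 0 and k_hot == 0:
        return [rna]
    hot_set = set(hot)
    normal = [i for i in range(n_bonds) if i not in hot_set]
    broken = []
    if k_norm:
        broken.extend(normal[i] for i in
                      rng.choice(len(normal), size=k_norm, replace=False))
    if k_hot:
        broken.extend(hot[i] for i in
                      rng.choice(len(hot), size=k_hot, replace=False))
    broken = sorted(set(int(b) for b in broken))

    # the replication complex, if any, is disrupted: nascent copies become
    # free molecules in their own right
    released = [RNAMolecule(seq=seg.product_sequence(), circular=seg.closed)
                for seg in rna.segments]
    rna.segments = []

    if rna.circular:
        _linearize(rna, broken[0])
        shift = (broken[0] + 1) % L
        broken = sorted((b - shift) % L for b in broken[1:])

    # split the linear chain after each broken bond
    cuts = [b + 1 for b in broken]
    starts = [0] + cuts
    ends = cuts + [L]
    fragments = [RNAMolecule(seq=rna.seq[s:e], circular=False)
                 for s, e in zip(starts, ends)]
    return fragments + released


def end_decay(
    rna: RNAMolecule,
    inside_protocell: bool,
    params: ParameterSet,
    rng: np.random.Generator,
) -> tuple[RNAMolecule | None, int]:
    """Terminal residues of a linear chain decay into nucleotide precursors.

    Each terminus independently loses its residue with ``P_NDE``
    (x ``F_DO`` outside a protocell).  Circular chains have no ends and
    are exempt.  Returns ``(molecule, Np released)``; the molecule is
    returned unchanged when nothing decays.  A chain reduced below
    length 2 is dissolved by the caller.  End decay of a template chain
    disrupts its replication complex: the phase driver releases the
    aligned fragments.
    """
    if rna.circular or len(rna.seq) == 0:
        return rna, 0
    p = params.P_NDE * (1.0 if inside_protocell else params.F_DO)
    p = min(p, 1.0)
    if p <= 0:
        return rna, 0
    released = 0
    lose_head = rng.random() < p
    lose_tail = len(rna.seq) > 1 and rng.random() < p
    if lose_head:
        rna.seq = rna.seq[1:]
        for seg in rna.segments:
            seg.start -= 1
        released += 1
    if lose_tail:
        rna.seq = rna.seq[:-1]
        released += 1
    if released:
        rna.invalidate_sequence_caches()
    return rna, released


# --------------------------------------------------------------------------
# Ligation / cyclization
# --------------------------------------------------------------------------

MIN_LOOP = 3  #: smallest chain that can close into a circle


def _free_linear(world: WorldState, room: int) -> list[RNAMolecule]:
    return [m for m in world.rna[room]
            if not m.circular and not m.is_template and not m.rep_bound]


def random_ligation_and_cyclization(
    world: WorldState, room: int, n_events: int | None = None
) -> None:
    """Spontaneous end-to-end joining within one compartment.

    Every free linear chain of length >= 3 closes into a circle with
    ``P_EL``.  Every unordered pair drawn from {free linear chains,
    free nucleotides} ligates end-to-end with ``P_RL``; the two possible
    concatenation orders are equally likely.  ``n_events`` lets the caller
    supply a pre-drawn ligation event count (vectorised across rooms).
    """
    params = world.params
    rng = world.rng

    loopable = [m for m in _free_linear(world, room)
                if len(m.seq) >= MIN_LOOP]
    if loopable and params.P_EL > 0:
        k = rng.binomial(len(loopable), min(params.P_EL, 1.0))
        for j in rng.choice(len(loopable), size=int(k), replace=False):
            mol = loopable[int(j)]
            mol.circular = True
            mol.invalidate_sequence_caches()

    chains = _free_linear(world, room)
    nt_counts = world.nt[room]
    k = len(chains) + int(nt_counts.sum())
    if k < 2:
        return
    if n_events is None:
        n_pairs = k * (k - 1) // 2
        n_events = rng.binomial(n_pairs, min(params.P_RL, 1.0))
    for _ in range(int(n_events)):
        chains = [m for m in chains if m in world.rna[room]]
        k = len(chains) + int(world.nt[room].sum())
        if k < 2:
            break
        picks = []
        for _ in range(2):
            k_now = len(chains) + int(world.nt[room].sum())
            idx = int(rng.integers(0, k_now))
            if idx < len(chains):
                mol = chains.pop(idx)
                world.rna[room].remove(mol)
                picks.append(mol.seq)
            else:
                weights = world.nt[room].astype(float)
                base = rng.choice(4, p=weights / weights.sum())
                world.nt[room, base] -= 1
                picks.append(BASES[base])
        a, b = picks
        joined = a + b if rng.random() < 0.5 else b + a
        world.add_rna(room, RNAMolecule(seq=joined))


# --------------------------------------------------------------------------
# Template-directed replication
# --------------------------------------------------------------------------

def _is_chromosome_length_match(mol: RNAMolecule, design: GenomeDesign) -> bool:
    sense = design.sense_sequence
    if len(mol.seq) != len(sense):
        return False
    canon = canonical_rotation(mol.seq)
    return canon in (canonical_rotation(sense),
                     canonical_rotation(design.antisense_sequence))


def become_template(world: WorldState, mol: RNAMolecule) -> None:
    """A free chain unfolds into template state.

    Circular chains convert with ``P_CRTT`` (the circle hinders folding,
    so it is almost always an open template); linear chains with
    ``P_LRTT``.  In linear-chromosome mode, full-length chromosome-sequence
    chains keep the chromosome's high conversion probability even though
    they are linear.
    """
    if mol.is_template or mol.rep_bound:
        return
    params = world.params
    if mol.circular:
        p = params.P_CRTT
    elif world.linear_chromosome_mode and _is_chromosome_length_match(mol, world.design):
        p = params.P_CRTT
    else:
        p = params.P_LRTT
    if world.rng.random() < p:
        mol.is_template = True


def _open_starts(template: RNAMolecule, frag_len: int) -> list[int]:
    """Admissible start positions for a fragment of ``frag_len``.

    With existing segments, only starts that abut a segment flank are
    admissible (the copy is assembled as one contiguous run of abutting
    pieces, to be consolidated by template-directed ligation); with no
    segment yet, any fit into uncovered positions is admissible.
    """
    L = len(template.seq)
    if frag_len > L:
        return []
    if not template.segments:
        last = L if template.circular else L - frag_len + 1
        return list(range(last))
    occ = template.covered_positions()
    if len(occ) + frag_len > L:
        return []

    def fits(start: int) -> bool:
        for j in range(frag_len):
            p = start + j
            if template.circular:
                p %= L
            elif not (0 <= p < L):
                return False
            if p in occ:
                return False
        return True

    anchors = set()
    for seg in template.segments:
        before = seg.start - frag_len
        after = seg.start + seg.r
        if template.circular:
            before %= L
            after %= L
        anchors.update((before, after))
    return sorted(a for a in anchors if 0 <= a and fits(a))


def _pairing_starts(template: RNAMolecule, sub_seq: str,
                    open_starts: list[int]) -> list[int]:
    """The subset of ``open_starts`` where every residue of the substrate is
    Watson-Crick complementary to the template (antiparallel register).

    Equivalent to finding the reverse complement of the substrate as a
    substring of the template at those starts, which C-level ``str.find``
    does far faster than per-residue comparison.
    """
    L = len(template.seq)
    pat = reverse_complement(sub_seq)
    hay = template.seq * 2 if template.circular else template.seq
    if len(open_starts) <= 4:
        return [s for s in open_starts if hay.startswith(pat, s)]
    matches = []
    i = hay.find(pat)
    while 0 <= i < L:
        matches.append(i)
        i = hay.find(pat, i + 1)
    if not matches:
        return []
    allowed = set(matches)
    return [s for s in open_starts if s in allowed]


def attract_substrate(world: WorldState, room: int,
                      template: RNAMolecule,
                      candidate: RNAMolecule | str | None = None) -> bool:
    """Try to base-pair one free substrate onto a template.

    Base pairing drives the alignment, antiparallel.  A template with
    aligned pieces accepts a substrate only at a flank of the existing
    run (the nascent copy stays contiguous); a bare template accepts a
    seed anywhere.  Among the admissible starts, one where every residue
    is Watson-Crick complementary is chosen uniformly (a released partial
    copy thus finds a matching register again); if none exists, a single
    uniformly chosen admissible start is tried, where each
    non-complementary residue must pass the per-residue false-pairing
    draw ``P_FP`` -- one failure rejects the whole substrate, which stays
    in the free pool.  ``candidate`` is a free linear RNA, a single base
    letter, or None (drawn uniformly from the compartment's free pool).
    Returns True if a segment was added.
    """
    params = world.params
    rng = world.rng

    if candidate is None:
        chains = [m for m in _free_linear(world, room) if m is not template]
        nt_total = int(world.nt[room].sum())
        k = len(chains) + nt_total
        if k == 0:
            return False
        idx = int(rng.integers(0, k))
        if idx < len(chains):
            candidate = chains[idx]
        else:
            weights = world.nt[room].astype(float)
            candidate = BASES[int(rng.choice(4, p=weights / weights.sum()))]
    sub_seq = candidate if isinstance(candidate, str) else candidate.seq

    open_starts = _open_starts(template, len(sub_seq))
    if not open_starts:
        return False
    L = len(template.seq)
    paired = _pairing_starts(template, sub_seq, open_starts)
    if paired:
        start = int(paired[rng.integers(0, len(paired))])
        bases = sub_seq[::-1]
        mism: tuple[bool, ...] = (False,) * len(sub_seq)
    else:
        start = int(open_starts[rng.integers(0, len(open_starts))])
        out = []
        flags = []
        for j in range(len(sub_seq)):
            p = (start + j) % L if template.circular else start + j
            res = sub_seq[len(sub_seq) - 1 - j]   # antiparallel alignment
            if COMPLEMENT[template.seq[p]] == res:
                flags.append(False)
            elif rng.random() < params.P_FP:
                flags.append(True)
            else:
                return False
            out.append(res)
        bases = "".join(out)
        mism = tuple(flags)

    # committed: remove the substrate from the free pool
    if isinstance(candidate, str):
        world.nt[room, BASE_INDEX[sub_seq]] -= 1
    else:
        world.rna[room].remove(candidate)
    template.segments.append(Segment(start=start, bases=bases, mismatch=mism))
    return True


class _MonomerSlots:
    """Per-template cache of the open positions a mononucleotide can take,
    keyed by the base that pairs there.  Rebuilt after each successful
    attachment; makes the (dominant) monomer attempts O(1)."""

    def __init__(self, template: RNAMolecule):
        self.template = template
        self.refresh()

    def refresh(self) -> None:
        tpl = self.template
        starts = _open_starts(tpl, 1)
        self.any_open = list(starts)
        by_base: dict[str, list[int]] = {b: [] for b in BASES}
        L = len(tpl.seq)
        for s in starts:
            by_base[COMPLEMENT[tpl.seq[s % L]]].append(s)
        self.by_base = by_base


def attraction_phase(world: WorldState, room: int,
                     templates: list[RNAMolecule]) -> None:
    """Substrate attraction for all templates of one compartment.

    Each template independently samples the compartment's free pool: every
    free nucleotide and free linear chain is drawn by each template with
    probability ``P_AT`` per step (a substrate captured by one template is
    no longer available to the next).  Placement and pairing follow
    :func:`attract_substrate`.  The per-kind attempt counts are single
    binomial draws, which keeps the phase cheap.
    """
    params = world.params
    rng = world.rng
    if not templates:
        return
    nt_row = world.nt[room]
    p_at = min(params.P_AT, 1.0)
    p_fp = params.P_FP

    order = rng.permutation(len(templates)) if len(templates) > 1 else [0]
    for ti in order:
        tpl = templates[int(ti)]
        if not tpl.is_template:
            continue
        slot = _MonomerSlots(tpl)
        if not slot.any_open:
            continue

        chains = _free_linear(world, room)
        if chains:
            k = rng.binomial(len(chains), p_at)
            if k:
                for j in rng.choice(len(chains), size=int(k), replace=False):
                    candidate = chains[int(j)]
                    if len(candidate.seq) > len(slot.any_open):
                        continue   # cannot fit in the remaining open space
                    if attract_substrate(world, room, tpl, candidate):
                        slot.refresh()

        # mononucleotides: one draw per base, O(1) per attempt
        for bi, base in enumerate(BASES):
            k = rng.binomial(int(nt_row[bi]), p_at)
            for _ in range(int(k)):
                paired = slot.by_base[base]
                if paired:
                    start = int(paired[rng.integers(0, len(paired))])
                    seg = Segment(start=start, bases=base, mismatch=(False,))
                elif slot.any_open and rng.random() < p_fp:
                    start = int(slot.any_open[rng.integers(0, len(slot.any_open))])
                    seg = Segment(start=start, bases=base, mismatch=(True,))
                else:
                    break
                nt_row[bi] -= 1
                tpl.segments.append(seg)
                slot.refresh()


def template_ligation(world: WorldState, template: RNAMolecule) -> None:
    """Join abutting aligned fragments; seal a complete circular copy.

    Each adjacent pair ligates with ``P_TL``, or ``P_TLR`` when a Rep is
    bound; in the Rep-catalysed case a false base pair flanking the
    junction additionally requires an independent ``P_FLR`` success.
    On a circular template, a single segment that covers every position
    may be sealed end-to-end by the same rule, after which the copy is
    released as a circular molecule.
    """
    params = world.params
    rng = world.rng
    L = len(template.seq)

    def attempt(flank_false: bool) -> bool:
        p = params.P_TLR if template.rep_bound else params.P_TL
        if rng.random() >= p:
            return False
        if template.rep_bound and flank_false and rng.random() >= params.P_FLR:
            return False
        return True

    merged = True
    while merged:
        merged = False
        by_start = {seg.start % L if template.circular else seg.start: seg
                    for seg in template.segments}
        for seg in list(template.segments):
            if seg not in template.segments:
                continue
            nxt_start = seg.start + seg.r
            if template.circular:
                nxt_start %= L
            other = by_start.get(nxt_start)
            if other is None or other is seg:
                continue
            if attempt(seg.mismatch[-1] or other.mismatch[0]):
                template.segments.remove(other)
                seg.bases += other.bases
                seg.mismatch = seg.mismatch + other.mismatch
                merged = True
                break

    if (template.circular and len(template.segments) == 1):
        seg = template.segments[0]
        if seg.r == L and not seg.closed:
            if attempt(seg.mismatch[-1] or seg.mismatch[0]):
                seg.closed = True


def rep_binding(world: WorldState, room: int, template: RNAMolecule,
                reps: list[RNAMolecule] | None = None) -> None:
    """Rep exchange on a template: drop with ``P_RD``, bind with ``P_RB``.

    Binding sequesters one active Rep from the compartment; while bound it
    is unavailable as catalyst or substrate elsewhere.  ``reps`` lets the
    caller share one scan for available Reps across the room's templates;
    a bound Rep is removed from it.
    """
    params = world.params
    rng = world.rng
    if template.rep_bound:
        if rng.random() < params.P_RD:
            rep = template.bound_rep
            template.bound_rep = None
            template.rep_bound = False
            if rep is not None:
                world.rna[room].append(rep)
        return
    if reps is None:
        reps = [m for m in world.rna[room]
                if "Rep" in active_ribozyme_roles(m, world.design)]
    if not reps:
        return
    if rng.random() < params.P_RB:
        # sequestration is by removal from the free pool; the rep itself
        # carries no flag so it is immediately active again once dropped
        rep = reps.pop(int(rng.integers(0, len(reps))))
        world.rna[room].remove(rep)
        template.bound_rep = rep
        template.rep_bound = True


def dissociation_probability(r: int, params: ParameterSet) -> float:
    """Probability that a duplex of ``r`` base pairs separates this step:
    ``P_SP ** sqrt(r)`` (cooperative unzipping makes longer duplexes
    disproportionately stable)."""
    if r < 1:
        raise ValueError("a duplex segment has at least one base pair")
    return params.P_SP ** math.sqrt(r)


def dissociation(world: WorldState, room: int, template: RNAMolecule) -> None:
    """Release whole duplex segments with probability ``P_SP ** sqrt(r)``.

    A released fragment re-enters the compartment's free pool: a 1-mer as
    a nucleotide, a sealed full circular copy as a circular RNA, anything
    else as a linear chain.
    """
    params = world.params
    rng = world.rng
    for seg in list(template.segments):
        if rng.random() < dissociation_probability(seg.r, params):
            template.segments.remove(seg)
            product = seg.product_sequence()
            world.add_rna(
                room, RNAMolecule(seq=product, circular=seg.closed)
            )


def classify_molecule(rna: RNAMolecule, design: GenomeDesign):
    """Identity of a molecule for the census.

    Circular chains are compared, rotation-invariantly, to the sense
    chromosome, the antisense chromosome and the control.  Linear chains
    are classified by their active ribozyme roles (a frozenset); anything
    else is ``"other"``.
    """
    if rna.circular:
        canon = canonical_rotation(rna.seq)
        if canon == canonical_rotation(design.sense_sequence):
            return "sense_chromosome"
        if canon == canonical_rotation(design.antisense_sequence):
            return "antisense_chromosome"
        if canon == canonical_rotation(design.control_sequence):
            return "control"
        return "other"
    roles = active_ribozyme_roles(rna, design)
    if roles:
        return frozenset(roles)
    return "other"


# --------------------------------------------------------------------------
# Per-room phase
# --------------------------------------------------------------------------

def _degradation_pass(world: WorldState, room: int) -> None:
    """Bond breaking and end decay for every chain of one room.

    All per-bond and per-end Bernoulli draws fall into three i.i.d. rate
    classes (plain bonds, F_IB-boosted U|G bonds, chain ends), so the
    number of events of each class is drawn as one aggregate binomial per
    room and the affected slots are then placed uniformly -- an exact,
    far cheaper equivalent of per-molecule draws.
    """
    mols = world.rna[room]
    if not mols:
        return
    params = world.params
    rng = world.rng
    inside = bool(world.occupied[room])
    fdo = 1.0 if inside else params.F_DO
    p_norm = min(params.P_BB * fdo, 1.0)
    p_hot = min(params.P_BB * params.F_IB * fdo, 1.0)
    p_end = min(params.P_NDE * fdo, 1.0)

    norm_counts = []
    hot_counts = []
    end_counts = []
    for m in mols:
        L = len(m.seq)
        hot = cleavage_sites(m)
        n_bonds = L if m.circular else L - 1
        norm_counts.append(n_bonds - len(hot))
        hot_counts.append(len(hot))
        end_counts.append(0 if m.circular else min(2, L))
    tot_norm = sum(norm_counts)
    tot_hot = sum(hot_counts)
    tot_end = sum(end_counts)

    k_norm = rng.binomial(tot_norm, p_norm) if tot_norm else 0
    k_hot = rng.binomial(tot_hot, p_hot) if tot_hot else 0
    k_end = rng.binomial(tot_end, p_end) if tot_end else 0
    if not (k_norm or k_hot or k_end):
        return

    def pick(total: int, k: int, counts: list[int]) -> dict[int, list[int]]:
        """Map molecule index -> local slot indices for k uniform picks."""
        chosen = rng.choice(total, size=k, replace=False)
        out: dict[int, list[int]] = {}
        bounds = np.cumsum(counts)
        for c in np.sort(chosen):
            i = int(np.searchsorted(bounds, c, side="right"))
            offset = c - (bounds[i - 1] if i else 0)
            out.setdefault(i, []).append(int(offset))
        return out

    norm_hits = pick(tot_norm, k_norm, norm_counts) if k_norm else {}
    hot_hits = pick(tot_hot, k_hot, hot_counts) if k_hot else {}
    end_hits = pick(tot_end, k_end, end_counts) if k_end else {}

    survivors: list[RNAMolecule] = []
    for i, mol in enumerate(mols):
        breaks = []
        if i in hot_hits:
            sites = cleavage_sites(mol)
            breaks.extend(sites[j] for j in hot_hits[i])
        if i in norm_hits:
            sites = set(cleavage_sites(mol))
            L = len(mol.seq)
            n_bonds = L if mol.circular else L - 1
            plain = [b for b in range(n_bonds) if b not in sites]
            breaks.extend(plain[j] for j in norm_hits[i])
        pieces: list[RNAMolecule]
        if breaks:
            pieces = _split_at(mol, sorted(set(breaks)))
            if mol.bound_rep is not None:       # complex disrupted
                pieces.append(mol.bound_rep)
                mol.bound_rep = None
                mol.rep_bound = False
        else:
            pieces = [mol]
            if i in end_hits:
                lose_head = 0 in end_hits[i]
                lose_tail = 1 in end_hits[i] and len(mol.seq) > 1
                lost = int(lose_head) + int(lose_tail)
                if lost:
                    if mol.segments or mol.bound_rep is not None:
                        for seg in mol.segments:
                            world.add_rna(room, RNAMolecule(
                                seq=seg.product_sequence(),
                                circular=seg.closed))
                        mol.segments = []
                        if mol.bound_rep is not None:
                            pieces.append(mol.bound_rep)
                            mol.bound_rep = None
                            mol.rep_bound = False
                        mol.is_template = False
                    if lose_head:
                        mol.seq = mol.seq[1:]
                    if lose_tail:
                        mol.seq = mol.seq[:-1]
                    mol.invalidate_sequence_caches()
                    world.np_[room] += lost
        for piece in pieces:
            if len(piece.seq) == 1:
                world.add_nucleotide(room, piece.seq)
            elif len(piece.seq) > 1:
                survivors.append(piece)
    world.rna[room] = survivors


def _split_at(rna: RNAMolecule, broken: list[int]) -> list[RNAMolecule]:
    """Split a chain at the given bonds, releasing any nascent copies."""
    L = len(rna.seq)
    released = [RNAMolecule(seq=seg.product_sequence(), circular=seg.closed)
                for seg in rna.segments]
    rna.segments = []
    if rna.circular:
        _linearize(rna, broken[0])
        shift = (broken[0] + 1) % L
        broken = sorted((b - shift) % L for b in broken[1:])
    cuts = [b + 1 for b in broken]
    starts = [0] + cuts
    ends = cuts + [L]
    return [RNAMolecule(seq=rna.seq[s:e], circular=False)
            for s, e in zip(starts, ends)] + released


def rna_phase(world: WorldState, room: int,
              n_ligation_events: int | None = None) -> None:
    """All RNA events of one room for one step, in fixed order:
    bond breaking and end decay, cyclization and random ligation, template
    conversion, Rep exchange, substrate attraction, template-directed
    ligation, duplex dissociation, and reversion of idle templates.
    """
    params = world.params
    rng = world.rng

    # 1-2. degradation ------------------------------------------------------
    _degradation_pass(world, room)

    # 3. cyclization + random ligation --------------------------------------
    random_ligation_and_cyclization(world, room, n_ligation_events)

    # 4. template conversion -------------------------------------------------
    mols = world.rna[room]
    n_lin = sum(1 for m in mols
                if not m.circular and not m.is_template and not m.rep_bound)
    n_circ = sum(1 for m in mols
                 if m.circular and not m.is_template and not m.rep_bound)
    special = world.linear_chromosome_mode
    if special or n_circ:
        for mol in mols:
            if mol.circular or (special
                                and _is_chromosome_length_match(mol, world.design)):
                become_template(world, mol)
                n_lin -= 0 if mol.circular else 1
    n_lin = max(n_lin, 0)
    if n_lin and params.P_LRTT > 0:
        k = rng.binomial(n_lin, min(params.P_LRTT, 1.0))
        if k:
            eligible = [m for m in mols
                        if not m.circular and not m.is_template
                        and not m.rep_bound
                        and not (special
                                 and _is_chromosome_length_match(m, world.design))]
            for j in rng.choice(len(eligible), size=min(k, len(eligible)),
                                replace=False):
                eligible[int(j)].is_template = True

    templates = [m for m in world.rna[room] if m.is_template]

    # 5-8. replication machinery --------------------------------------------
    if templates:
        free_reps = [m for m in world.rna[room]
                     if "Rep" in active_ribozyme_roles(m, world.design)]
        for tpl in templates:
            rep_binding(world, room, tpl, free_reps)
    attraction_phase(world, room, templates)
    for tpl in templates:
        template_ligation(world, tpl)
    for tpl in templates:
        dissociation(world, room, tpl)

    # 9. reversion of idle templates ----------------------------------------
    for tpl in templates:
        if tpl.is_template and not tpl.segments and not tpl.rep_bound:
            tpl.is_template = False
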