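# Model and methods

## The system

The simulator is an agent-based Monte-Carlo model of RNA-based protocells
on an `N x N` toroidal grid.  A grid room holds either a free pool of
molecules or exactly one protocell, whose membrane of `b` amphiphiles
encloses the room's pools.  Resolution is the single monomer: every
nucleotide and amphiphile is counted, every RNA chain is an individual
object with an explicit base sequence.  Each simulation step, every
possible event fires independently with its per-step probability
(`ParameterSet`); a molecule undergoes at most one transformation per
step.  A single seeded generator (`numpy.random.Generator`, PCG64) drives
every draw in a fixed documented order, so runs are bit-reproducible.

Step order: (1) small-molecule chemistry in every room (vectorised);
(2) RNA events room by room, in a freshly randomised room order —
degradation, cyclization/ligation, template conversion, Rep exchange,
substrate attraction, template-directed ligation, duplex dissociation,
reversion of idle templates; (3) protocell events — membrane formation,
amphiphile exchange, permeation, division, fusion, breakage; (4) the
movement phase.

## Chemistry and catalysis

Two reversible chains, `Npp <-> Np <-> Nt(A|U|G|C)` and `Ap <-> Am`, with
uncatalysed forward rates and fast catalysed rates when the matching
synthetase ribozyme (Npsr, Nsr, Asr) is present in the same compartment.
Catalysis is presence-based with unlimited turnover: one active ribozyme
switches every eligible substrate of its compartment to the catalysed
probability for that step.  Degradative events run `F_DO`-fold faster
outside protocells (higher water activity).  Competing fates of one pool
are drawn as a single multinomial split, all on the step-entry counts.

## RNA replication

Replication is ligase-based assembly, not processive polymerisation.  An
unfolded chain (template state, entered with `P_CRTT` for circles and
`P_LRTT` for linear chains) attracts free nucleotides and oligomers by
base-pairing; abutting aligned pieces are joined by template-directed
ligation — slow alone (`P_TL`), fast with a Rep replicase bound
(`P_TLR`, with the `P_FLR` gate when a flanking pair is false); duplex
segments fall off whole with `P_SP^sqrt(r)`.  Specific readings the text
of the model leaves open, decided here:

* **Attraction is per substrate and per template.**  Each template
  independently draws each free nucleotide/oligomer of its compartment
  with `P_AT` per step.  A one-attempt-per-template reading was tried and
  discarded: against `P_SP^sqrt(1)` = 0.5 dissociation of single-residue
  seeds it can essentially never assemble a 32-mer, so the model would
  have no replication at all.
* **Pairing drives placement.**  A substrate anneals at a uniformly
  chosen admissible start where it is perfectly complementary; if none
  exists, one random admissible start is tried with the per-residue
  false-pairing tolerance `P_FP`.  (Random-register placement was tried
  and discarded: released partial copies can then never find a matching
  register again, and the feedstock drains irreversibly into short dead
  oligomers.)
* **The nascent copy is contiguous.**  With aligned pieces present, new
  substrates may only extend a flank of the existing run.  Allowing
  independent seeds at arbitrary registers produces tiling frustration —
  overlapping fragments block each other and no copy can complete.
* **A full-circle copy is sealed, and released circular.**  When the run
  covers all positions of a circular template, one further
  template-directed ligation closes the copy end-to-end.  This is the
  model's route from circular chromosome to circular copies; spontaneous
  cyclization of full-length transcripts (`P_EL` = 1e-7) is orders of
  magnitude too rare to sustain any circular population, and
  rolling-circle synthesis is excluded (products never exceed the
  template length).  Products of linear templates are always linear.
* **Degradation ignores the duplex.**  Bond breaking (with the `F_IB`
  boost at U|G sites of linear chains) and end decay apply to templates
  too; a hit disrupts the complex, releasing the nascent pieces as free
  molecules.  Exempting duplexed regions was tried and discarded: it
  shields the linear chromosome from the self-cleavage that the
  circular-vs-linear contrast rests on.
* Template reversion: a template with no aligned pieces and no bound Rep
  refolds at the end of the step, so `P_LRTT`/`P_CRTT` act as per-step
  re-unfolding probabilities.
* A Rep bound to a template is sequestered: unavailable as catalyst or
  substrate until it drops (`P_RD`).
* Minimum loop for cyclization: 3 residues (the model text is silent;
  this merely excludes degenerate 1-2-residue circles).
* Ribozyme activity requires the sense-orientation domain in a linear,
  folded (non-template) chain shorter than 1.5 x the domain.

Aggregate-draw equivalence: per-bond, per-end and per-molecule Bernoulli
draws within one room fall into a handful of i.i.d. rate classes, so the
number of events per class is drawn as one binomial and the affected
slots placed uniformly — exactly equivalent to per-molecule draws and an
order of magnitude cheaper.

## Membranes and protocells

`b/2` is the surface proxy, `(b/2)^(3/2)` the volume proxy, and
`n / (b/2)^(3/2)` — with `n` the interior impermeable content (free
nucleotides plus all RNA residues) — the interior "ion concentration"
that damps amphiphile loss (`F_OP`) and the influx of the charged
precursors (`F_DE`); uncharged amphiphile precursors are not Donnan
damped.  Outward permeation uses the plain base probability (the inward
formulas have no stated outward counterpart; a minimal symmetric
completion).  Division splits membrane and contents binomially (p = 1/2)
and places one offspring in an adjacent protocell-free room, pushing that
room's free molecules into its own free neighbours; the attempt aborts if
geometry forbids it.  Molecules never cross a membrane by diffusion;
inoculated protocells carry exactly `L_AM` membrane amphiphiles.

## Experiments

The reference system: 40 x 40 grid, 8e4 Npp and 6e4 Ap scattered
uniformly at step 0; 10 empty protocells inoculated at step 1e3; at step
1e4, 10 diagonal rooms receive protocells with 5 copies of each ribozyme
plus 5 circular sense chromosomes, and 10 other diagonal rooms the same
with the functionless control circle instead.  "Spread" is classified
from the census series: the sense-chain count holds at or above a
threshold (default 50) over the final tenth of the samples.  The
linear-chromosome comparison keeps the chromosome's high template
conversion (`P_CRTT`) for full-length linear chromosome-sequence chains
but exposes them to end decay and to their own inter-gene self-cleavage.

### The scaled preset, and what passing tests show

Full reference runs (2e6 steps, 40 x 40) take hours.  `scaled_config`
reduces every extensive quantity ~10-fold (169 rooms, 8e3/6e3 feedstock,
3+3 seeded cells, 2e4 steps) while preserving the intensive ones:
per-room molecule density, the membrane size `L_AM` (hence the
osmotic/Donnan concentration scale), and the grid fraction a full
protocell population can cover (`T_APB / L_AM` = 10 cells on 169 rooms).
Inoculations happen at steps 500/3000 rather than a strict 1/10 of the
reference steps, because the feedstock's chemical relaxation runs on
per-molecule timescales that do not shrink with system size.  The scaled
spread threshold is 30 = 2 x the 15 seeded sense copies: the population
must at least double over its inoculum and hold that level.  The test
suite runs this preset for 6,000 steps with five seeds per condition (a
problem-size choice; the preset default is 20,000).

Per-molecule kinetics are scale-free in time, so scaling the step budget
compresses the observation window, not the dynamics.  Within these
horizons the simulations show: sustained replication of the circular
chromosome (antisense copies, regenerated ribozymes, persistence of the
sense chain near its inoculum) and the collapse of the linear chromosome
under end decay plus self-cleavage.  They do not show the reference
system's long-horizon features — the many-fold amplification of the
sense chain to a high balance level, and the eventual decline of the
control, which only separates from the chromosome once the ribozymes
seeded alongside it have decayed (a >~5e4-step process).  Under this
implementation's kinetics the sense count in the scaled window sustains
but does not double, so the strict all-seeds-spread check fails there;
the circular-vs-linear contrast is asserted on the raw counts as well.

## Known limitations

* The synthetic world has no sequence-structure model: folding,
  activity and self-cleavage are abstracted into probabilities and the
  two-residue U|G site label.
* Interior molecule counts are unbounded (no volume exclusion beyond the
  permeation/osmotic proxies).
* The sense/antisense balance of completed copies is asymmetric (sense
  partials cleave; antisense partials recycle), which depresses the
  sense-specific count relative to the chromosome population as a whole.
* Movement aborts into occupied rooms rather than re-drawing a target,
  and fusion scans unordered adjacent pairs once per step.
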