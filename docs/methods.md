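# Methods

This note records the modeling conventions, numerical choices and problem
sizes behind `simbias`, in the order the pipeline uses them. Wherever the
underlying model admits more than one reasonable reading, the choice made
here is stated explicitly together with its rationale; the test suite pins
each one.

## Polyomino self-assembly map

A genotype of the S(n, 4n) map is a binary string of length L = 4·n·b read
as n tiles × 4 edges × b-bit colors, big-endian, edge order (N, E, S, W).
Orientation k rotates a tile by 90k° clockwise, i.e. cyclically shifts its
color quadruple; the color facing direction d under orientation o is
`colors[(d − o) mod 4]`. Colors bond in the unique pairs (1, 2), (3, 4), …;
color 0 and the maximal color 2^b − 1 are neutral. Any fixed edge-order and
rotation convention gives the same map up to genome relabeling.

Assembly seeds one copy of the first-encoded tile, orientation 0, at the
origin (a configuration flag seeds from a uniformly random tile instead;
off by default). A *move* is a distinct (empty site, tile type,
orientation) triple that would form ≥ 1 bond to the placed structure;
duplicates arising from multiple bonding neighbors count once, and the
next move is drawn uniformly over distinct available moves. Non-bonding
adjacencies of a newly placed tile are permitted — only one new bond is
required, and no mismatch constraint exists. Tile copies are unlimited.
Assembly terminates when no move exists; if the structure's bounding box
ever exceeds cutoff × cutoff (default 16 × 16) the run is *unbounded*.

Determinization repeats assembly 20 times (configurable). Repeats compare
**canonical free shapes** (up to translation, rotation and reflection), the
same equivalence used for phenotypes; a genotype whose repeats disagree, or
with any unbounded repeat, maps to UND. A run during which the move set
never offered a choice is provably deterministic, so remaining repeats are
skipped — a pure optimization with identical semantics. Each repeat uses an
independent RNG substream; the base seed is a CRC-32 digest of the decoded
tile colors XORed with the experiment's master seed, which makes
genotype → phenotype a deterministic function, independent of evaluation
order and batch size (tables are exactly reproducible from one seed).

The assembly, canonicalization and counting inner loops are numba-compiled
array kernels (`_kernels.py`) with a semantically identical pure-Python
fallback; one random S(16, 64) genotype evaluates in tens of microseconds,
which is what makes 10⁶-genome sampling and hundreds of evolutionary runs
routine on one core.

## Shape canonicalization, symmetry and enumeration

The canonical form of a cell set is the lexicographically smallest
translation-normalized sorted cell list over the 8 dihedral transforms of
the square; it is idempotent and shared bit-for-bit between the Python and
kernel implementations. The symmetry class is the conjugacy class of the
stabilizer subgroup: C1, C2, C4, D1, D2, D4, with the axis/diagonal flavor
of D1/D2 retained as metadata but collapsed in reports.

Three enumeration routes:

* **Growth enumeration** (`free_shapes`): explicit canonical
  deduplication, budget-limited to n ≤ 12; used as the small-n oracle.
* **Exact counts** (`enumerate_free`): Redelmeier depth-first counting of
  fixed polyominoes (iterative, with per-level extension buffers) plus a
  Burnside correction over the dihedral group. The 7 symmetric Burnside
  terms — translation classes invariant under a 90° or 180° rotation, an
  axis mirror or a diagonal mirror — come from the orbit construction
  below and are cheap because symmetric shapes are rare. n = 16 runs in
  about 80 s on one core (the 104,592,937 fixed 16-ominoes take ~2 s in
  the compiled kernel; the centrosymmetric enumeration dominates).
* **Invariant shapes** (`enumerate_invariant`): all free n-ominoes whose
  stabilizer contains a given group, built directly as connected unions of
  symmetry orbits. Symmetry centers live on the doubled lattice (cell
  centers, lattice vertices, edge midpoints); fourfold centers must be
  cell centers or vertices — 90° rotation about an edge midpoint does not
  map cells to cells. Orbit unions are enumerated once each by a
  minimum-indexed-root connected-subgraph search over the orbit-adjacency
  graph, then filtered by true cell-level connectivity (orbit-graph
  connectivity is necessary but not sufficient). The candidate universe is
  a disc of doubled radius 2n + 8: a connected shape invariant under a
  rotation must approach its center — a symmetric closed loop through any
  cell and its image has odd winding number about the center or encircles
  it as a ring of ≥ 8d cells at distance d — so every cell lies within
  n/2 + 2(n − 1) doubled units of the center. Mirror groups, which leave a
  translation degree of freedom along the axis, are rooted at axis-touching
  orbits with minimal along-axis coordinate instead.

This is how the 17 fourfold-symmetric 16-mers (5 D4 + 12 C4) are produced
in ~0.1 s without touching the 13-million-shape morphospace, and the route
the acceptance script uses.

## Probability estimation and the envelope

`estimate_phenotype_frequencies` draws genomes uniformly over all 2^L bit
strings (equivalently, every color independently uniform), tallies UND
separately and normalizes probabilities over non-UND outcomes only.
Low-frequency widening from finite sampling is *not* corrected; raw counts
are reported.

Minimal-genome interface complexity of a phenotype: for each of up to
`budget` sampled generating genotypes, scan interface loci in ascending
(tile, edge) order, set each to the neutral color 0 whenever the phenotype
is unchanged, repeat to a fixed point, then count the distinct colors still
participating in a realized bond of the assembled structure; report the
minimum over genotypes. Each surface counts separately (a bonded color
pair contributes 2), matching the interface-type convention for protein
complexes where an asymmetric interface has two distinct surfaces. The
estimate is monotonically nonincreasing in the budget; on the fully
enumerable S(2, 4) map the greedy fixed point attains the exhaustive
minimum for every phenotype (test-verified). Analysis tables use phenotypes
observed ≥ 10 times and a budget of 5 genotypes each — complexity estimates
for rarer phenotypes are both noisy and expensive, and the default budget
of 100 is available where fidelity matters more than runtime.

The envelope fit is a documented convention, not a canonical estimator:
bin records by integer complexity, least-squares fit log₂(max probability
per bin) against the bin, clip the slope at a ≥ 0, then shift b minimally
so *no* record violates P ≤ 2^(−aK̃−b). By construction the fitted bound
has zero violations on its input.

## Evolutionary protocol

Populations of N genomes; fitness-proportionate (roulette) selection with
replacement, N draws per generation; clones then mutate; no crossover or
elitism. UND → fitness 0 under every protocol; unit → 1 for any shape;
random → per-shape value drawn uniformly on [0, 1] lazily, cached for the
run and redrawn between runs; size → 1/(|s − s*| + 1).

The mutation rate μ is interpreted as **expected mutations per genome per
generation**, applied per locus at rate μ/L (flag `per_locus=True` applies
μ at each locus literally; at μ = 0.1 on L = 384 that regime is
mutationally catastrophic, which is why it is not the default). Mutations
are placed by drawing the binomial total and uniform distinct positions
across the population — equivalent to independent per-locus flips.

Fixation is not uniquely defined for a mutation–selection balance, so it is
operationalized: the run's fixed structure is the first phenotype at the
fitness optimum (size s* under size fitness; any non-UND shape otherwise)
carried by > `fixation_share` (default 0.5) of the population for
`fixation_hold` (default 10) consecutive generations. The headline D4/C4
prevalence measured by the acceptance pipeline is insensitive to these
knobs: share 0.5/hold 10, share 0.5/hold 50 and share 0.9/hold 10 agree to
within half a percentage point at 300 runs. Initial populations are N
i.i.d. uniform random genomes. Phenotypes are memoized per genotype within
a run (exact, because the genotype → phenotype map is deterministic; see
above). Runs hitting `max_generations` (default 5000; at that horizon
essentially every S(16, 64) size-fitness run has fixed) are reported as
timeouts, distinct from extinctions (all-zero fitness).

## Interaction-graph topologies

A complex is a connected typed graph; interface types carry a
symmetric/asymmetric flag when homomeric. K̃ counts distinct binding
surfaces: +1 per symmetric homomeric type, +2 per asymmetric or heterotypic
type, 0 for a monomer. Permutation symmetry checks all node permutations
(≤ 8 nodes) preserving types, adjacency, interface identities and the
surface orientation of asymmetric edges; the 6-mer category is the largest
k ∈ {6, 3, 2} admitting a fixed-point-free automorphism with uniform cycle
length k. Sixfold rings and threefold prisms both admit a single-6-cycle
automorphism, so C6 and D3 genuinely collapse; automorphism groups larger
than any planar ring symmetry (order > 12, e.g. stars) fall back to the
largest compatible cyclic category with a warning. The 6-mer morphospace
enumerates connected typed graphs up to isomorphism and type relabeling
with one interface type per subunit-type pair and no multi-edges (a
configuration simplification; graphs with several interface types between
one pair can still be built and analyzed directly).

## RNA structures

Dot-bracket structures are validated with positions on error; pseudoknots
are outside the model. Encodings: `.`→00, `(`→10, `)`→01 (so length
exactly doubles), and for level-5 shapes `[`→0, `]`→1 with the trivial
shape `_` → "0". The level-5 coarse-grainer drops unpaired positions,
builds the base-pair nesting tree and contracts unary chains, so each
maximal stem — helices separated only by bulges and internal loops —
becomes one bracket pair around its branches. This reproduces the stem
arrangement of the abstract-shape hierarchy's top level but is an
approximation of the reference RNAshapes tool; exact tool parity at
external-loop edge cases is not guaranteed, and pre-coarse-grained shape
strings can be supplied instead. Folding itself is delegated to external
engines (structure lists in, tables out).

## Time-series phenotypes

The generator is a three-variable Goodwin-type negative-feedback loop
(production under steep cooperative repression, two linear relay steps,
linear decay; 8 parameters), integrated by fixed-step RK4 at dt/4
sub-steps for 1000 recorded steps of 1 minute from fixed initial
conditions. Wild-type rates 0.04 min⁻¹ put the limit-cycle period near 90
steps (measured 96, stable under step halving); Hill exponent 10 is
comfortably above the oscillation threshold, so the 0.25–2.00
multiplicative parameter grid (8 values, uniform, independent per
parameter) straddles the Hopf boundary and produces oscillatory, damped
and monotone responses. The oscillator is a synthetic stand-in — it is not
a model of any specific regulatory network — and externally simulated
concentration curves can enter the same pipeline via CSV.

Period detection takes the first local autocorrelation maximum with
normalized value ≥ 0.5 after discarding the first half of the series;
flat-tailed or peak-free (damped/monotone/chaotic) series raise an
aperiodic flag and are tallied separately rather than silently encoded.
One full oscillation starting after a one-period transient (configurable)
is resampled to exactly 50 points by linear interpolation — curves equal up
to a uniform time dilation therefore coarse-grain to nearly identical
profiles — and discretized by slope sign (dy/dt ≥ 0 → 1, ties inclusive),
giving 49-bit phenotype strings whose complexity is the LZ measure.

What the generator does *not* emulate: real regulatory networks' dimension
(tens of coupled equations), stiffness, multistability, and biologically
structured parameter correlations. Passing tests therefore demonstrate the
pipeline's correctness and the genericity of simplicity bias in a
negative-feedback oscillator family, not quantitative claims about any
particular organism's network.

## Problem sizes used by the tests and acceptance script

Chosen so the full suite and the acceptance script each finish comfortably
on one core: exhaustive oracles at map sizes S(1, 4)/S(2, 4)/S(2, 8) and
string lengths ≤ 12; sampling at 10⁶ genomes for S(16, 64) and 10⁵ for
S(2, 8); 110–150 evolutionary runs at the headline parameters (N = 100,
μ = 0.1, s* = 16) and 200–500 neutral runs on S(2, 8); enumeration
cross-checks at n ≤ 10 with the n = 16 count verified once in a longer
run. The LZ76 parser is verified against an independent reference
implementation on all 8190 binary strings of length ≤ 12.

## Known limitations

* The measured D4/C4 share of fixed 16-mers depends in principle on the
  operational definition of fixation; the definition here (majority held
  for 10 generations at the optimum) is one documented choice, though the
  measured value is empirically insensitive to the share/hold knobs.
* Minimal-interface complexity is an upper estimate at small budgets; it
  only converges to the true minimum as sampling grows (exactly verified
  on fully enumerable maps).
* The level-5 coarse-grainer and the permutation-symmetry categories are
  documented approximations (see above), adequate for the package's own
  analyses but not drop-in replacements for the reference tools.
* Numba is effectively required at headline problem sizes; the pure-Python
  fallback is for correctness checking and tiny maps.
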