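# Methods

This note documents the models and conventions implemented in
`oligotrace`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not establish about real data.

## Reconstruction model

A traced cell is a forest of SWC sample points (id, structure code,
x/y/z in µm, radius in µm, parent). Multiple roots are legal and
meaningful: injured cells present as several connected components.
Components are enumerated deterministically by ascending minimum sample
id. Validation rejects duplicate ids, non-positive radii, non-finite
coordinates, dangling parents and cycles, each with the offending sample
named. Files written by the package use shortest round-trip float
formatting, so read→write→read is the identity on points.

Cells lacking a structure-code-1 (soma) point are analysed by treating
the root of the largest component as a soma surrogate, with a logged
warning — some tracing exports omit soma codes and the analysis must not
silently fail on them. Coordinates are assumed to be micrometres unless
a `unit_scale` is configured.

## Arbor decomposition

Zero-length duplicate points (within 10⁻⁶ µm of their parent, a common
tracing artifact) are merged before decomposition. One *process arbor*
is created per neurite point whose parent is a soma point. A *branch
segment* runs from a topological node (soma attachment or junction with
≥ 2 children) to the next junction or tip; the attachment node is
included in the chain, so segment lengths tile the arbor's path length
exactly. A segment's median radius is taken over its own (non-shared)
points.

Branch ordering is **centrifugal**: the soma-attached segment is order
1 and the order increments at every junction moving outward.
Trifurcations are a single branch point whose three children all take
order +1. Strahler ordering is deliberately not used: initiation-order
statistics in this field are reported on the centrifugal scale, where
first-order initiations are meaningful.

Two reporting ambiguities are resolved by emitting both aggregations
rather than choosing silently:

- *Total branches* (TB) defaults to counting every branch segment
  (`all_segments`); a `terminal_tips` mode counts only tip-terminated
  segments. The mode is recorded in every output.
- *Arbor length* is emitted both as total path length per arbor and as
  the longest root-to-tip path; *branch points* both per cell and as a
  per-arbor mean.

## Internode identification

A putative internode is a thickened, longitudinal run of branch
segments reached from a fine connecting branch. Two classification
modes exist because deposited reconstructions may or may not delimit
internodes explicitly:

- **annotation** — a segment is myelinating (M_PB) iff > 50% of its own
  points carry the annotation structure code (default 7). Requesting
  annotation mode on a cell with no annotated points is an error rather
  than a silent zero-internode result.
- **criteria** — a candidate run starts at a segment whose median
  radius is at least `radius_ratio` (default 2.0) times its parent's,
  and extends through children of comparable thickness (within the same
  factor). The run is accepted iff its total path length reaches
  `min_length_um` (default 25 µm, just below the ~29 µm detection floor
  for putative internodes in this preparation) and its main path's
  straightness (chord / path length, measured along the longest
  root-to-tip path within the run) is at least `min_straightness`
  (default 0.8).

The default mode (`auto`) uses annotations when present. All three
criteria values are configuration-exposed and echoed into a JSON
provenance sidecar next to every output table, because classification
results are only interpretable jointly with the criteria that produced
them.

Because a run start requires a parent segment to compare against,
criteria mode cannot classify a soma-attached (order-1) segment as
myelinating; first-order internodes are reachable in annotation mode
only. Fine branches sprouting from an internode are classified
independently and do not split it; contiguous myelinating segments merge
into a single internode unless separated by a non-myelinating connecting
branch. Internode length is the path length of the merged run, not its
chord, consistent with every other length in the package.

The maturation ratios use the same denominator — `m_pb_over_tb` is the
number of M_PB segments over TB and `nm_pb_over_tb` its complement — so
they sum to 1 exactly.

### Spatial envelope

The white-matter axis is estimated as the first principal direction of
the internode points projected to the XY plane (sign-normalised to
positive x); a fixed axis may be supplied instead when the tract
orientation is known. The envelope is the extent of the internode cloud
along the in-plane orthogonal direction and along z. Note that when the
point cloud is not exactly axis-aligned the principal direction differs
slightly from the x-axis and the perpendicular extent differs
accordingly from the raw y-range.

## Colocalization

Both channels are maximum-projected and thresholded independently
(Otsu by default; a fixed threshold is available and required for
degenerate constant images; the method and value are always recorded).
The two reported metrics are the NF200 pixel fraction (percent of image
area) and MBP∧NF200 / NF200. Normalising the overlap to the NF200 area
makes the myelination measure invariant to MBP signal outside axons and
insensitive to changes in axonal density itself. Overlap is counted at
pixel level; an optional dilation radius (default 0) can absorb
chromatic offset between channels. An empty NF200 mask leaves the ratio
undefined (reported as absent with a warning) rather than zero.

## Statistics

Per metric and per comparison, both samples are tested with
Shapiro–Wilk (α = 0.05). If both pass, groups are compared with a
two-sided unpaired *t* test and summarised as mean ± SEM; otherwise
with a two-sided Mann–Whitney *U* (exact null distribution when the
combined n ≤ 20 and there are no ties, normal approximation with tie
correction otherwise) and summarised as median (Q1–Q3). The *t* test
defaults to the classic equal-variance form with a Welch switch, and
the variant used is recorded — the choice is ambiguous in common
practice and should be visible, not silent. No multiple-testing
correction is applied, and the report metadata says so. Comparison of
two metric tables is refused when their criteria provenance differs.

## Synthetic-data generator

The generator emulates the study conditions rather than fitting any
particular cell. Per cell:

1. **Topology.** The arbor count is a rounded normal (mean 7.7, sd 1.6,
   min 3). Each arbor grows by a branching process in which a branch at
   order *o* bifurcates with probability p₀·decay^(o−1) up to order 9.
   The constants (control p₀ = 0.38, decay = 0.82; activity-blockade
   p₀ = 0.46, decay = 0.80) put the expected TB near 20 and 25
   respectively, reproducing the ~20% branch surplus of chronically
   silenced cells. Every internal node bifurcates, so generator
   branches map one-to-one onto decomposed branch segments.
2. **Internode placement.** A quota of round(m_pb_fraction · TB ·
   placement_probability) branches is drawn at random from the eligible
   set (order ≥ 2, parent not an internode), so the per-cell M_PB/TB
   ratio is controlled by construction (control 0.28, blockade 0.20).
   If no eligible branch exists the generator forces one bifurcation —
   a transitional OL carries at least one internode by definition.
   Lengths are lognormal; the log-scale sigma is set from the reported
   interquartile ranges (control: median 85 µm, sigma 0.293; blockade:
   median 54 µm, sigma 0.542). Draws are floored at 29 µm — the
   shortest putative internode detectable in this preparation — and the
   lognormal location is adjusted so the *post-floor* median equals the
   configured value, since the configured medians are themselves
   medians of detected internodes.
3. **Geometry.** Fine branches (radius 0.3 µm, lognormal lengths,
   median 12 µm) grow as persistent random walks; internodes (radius
   1.2 µm) run along ±x with small angular jitter (default 1.5°) and
   carry the annotation code. Each connecting branch that feeds
   internodes is steered to an assigned transverse (y, z) position;
   those positions tile the configured envelope cross-section
   (36.5 × 17.3 µm) and internode points are clamped to it, so the
   configured extents are realised whenever at least two connecting
   branches exist. Interconnected internodes (internode → fine
   connector → internode) arise naturally from the eligibility rule.

The injury transform deletes each internode branch (with its distal
subtree) with probability 1 by default — injured cells show no
identifiable internodes — and detaches surviving branch segments into
new components with probability 0.3, recording the resulting fragment
count in the truth.

All sampling flows through one seeded generator; identical parameters
reproduce byte-identical SWC files, image arrays and truth records.

**What the generator does not emulate.** Branch orders top out around
4–5 rather than the 7+ seen in real traced cells: with strictly
bifurcating ~20-segment cells spread over ~8 arbors, deep order chains
are combinatorially inaccessible, and matching both TB and maximum
order simultaneously would require non-bifurcating order conventions.
It also produces no tracing noise (gaps, duplicate points beyond the
merge tolerance, radius jitter) and no membrane-bubble artifacts.
Passing parameter-recovery tests therefore demonstrates that the
pipeline measures what the generator encodes — lengths, classes,
orders, envelopes, fragments, coverage — not that the criteria defaults
are optimal for any particular real tracing.

The image generator draws near-horizontal fibers of configurable width
across a 3-plane stack (fiber intensity 160, background 12, Gaussian
noise sd 3) and covers a contiguous fraction *f* of each fiber's pixels
with myelin signal; crossing pixels are assigned to the first-drawn
fiber so the realised coverage equals *f* without double counting.

## Problem sizes and numerical choices

The replicate analyses use 12 cells per condition cohort — the cohort
size of the original control study — with 100 replicate cohort draws
for the effect-direction rate, 50 cells for length-median recovery, and
20 image pairs for coverage recovery. The effect-direction check treats
the two directional effects (internode length down, NM_PB/TB up) as
reproduced when they hold in ≥ 95% of draws; the arbor-count
comparison, whose two conditions are drawn from the same distribution,
is instead required to stay *below* a 10% significance rate, since a
correctly calibrated α = 0.05 test flags ~5% of identical-distribution
draws by construction and demanding non-significance in ≥ 95% of draws
would reject a correct implementation about half the time.

Duplicate-point merging uses a 10⁻⁶ µm tolerance. Envelope axes are
sign-normalised (positive x, ties broken toward positive y) for
determinism; degenerate single-point clouds take axis (1, 0). Exact
Mann–Whitney p-values are used only in the no-ties small-sample regime
where the permutation null is exact. Segment and arbor orderings are
deterministic everywhere (ascending sample ids / BFS order), so all
outputs are stable across runs.

## Known limitations

- Criteria-mode classification cannot produce first-order internodes
  (see above); initiation-order minima from criteria mode are therefore
  ≥ 2 even where annotation-based analysis would report 1.
- The geometric criteria defaults are reconstructions from the
  published description of internodes (thickened, longitudinal, above
  the detection floor), not values lifted from a protocol; analyses of
  real data should treat them as a starting point and always read them
  together with the emitted provenance sidecar.
- Internode thickness / g-ratio estimation, Sholl analysis and
  node-of-Ranvier detection are out of scope.
- The colocalization module quantifies exactly two metrics; it is not a
  general colocalization suite (no Manders/Pearson coefficients,
  deconvolution or background-subtraction pipelines).
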