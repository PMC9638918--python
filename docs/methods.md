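# Methods

`pdupack` models and analyses an experiment in which a transcription
repressor directs a chosen DNA segment into a Pdu bacterial microcompartment
(MCP): LacI (optionally together with a non-cleavable *B. thuringiensis*
LexA) binds a cluster of operators on a low-copy target plasmid, the bound
nucleoprotein is enclosed during shell assembly, host nucleases degrade the
unprotected extrachromosomal DNA, and sequencing of the DNA recovered from
purified compartments shows the operator segment massively enriched.  The
package provides the generative model of that process, the coverage and
enrichment statistics used to read it out, and the SPR binding analysis of
the repressor–operator interaction.

## Sample model

A sample is a chromosome plus two plasmids.  Defaults: a 100-kb synthetic
chromosome at copy number 1 (a stand-in for the 4.6-Mb *E. coli*
chromosome; background sampling is weighted by copy number × length, so
only the relative weights matter, but absolute percentages are therefore
larger than they would be against a full-length chromosome), an 8-kb
helper plasmid at copy number 9 (p15A-like), and the 5-kb target plasmid at
copy number 2 (RK2-like).  Three target architectures are built:

* `lacO5` — five 21-bp LacI operators and a promoter spacer inside a 594-bp
  region between the inner edges of two 18-bp I-SceI sites;
* `lacO8` — eight LacI operators after a single I-SceI site;
* `lexA` — (lacO)₂-(lexA_BT)₂-(lacO)₂ between two I-SceI sites.

The 600-bp analysis segment covers the operator cluster; for the
two-I-SceI designs it spans the 594-bp excisable region plus 3 bp on each
side, so the repressor sites always lie inside it while the I-SceI sites
straddle its edges.  Backbones are random at a fixed seed; the LacI motif
is the symmetrised lac operator and the I-SceI motif the canonical 18-mer,
while the 14-bp LexA_BT motif is a synthetic placeholder (the authentic
operator is not modelled).  Authentic plasmid sequences can be supplied as
FASTA without code changes.  Replicons are treated as linear: the analysed
segments are interior, and this avoids circular-coordinate ambiguity.

## Protection, degradation, and reads

`molecule_count` plasmid molecules (default 1000) are allocated across
plasmids in proportion to copy number.  On each molecule every repressor
site is bound independently with probability `p_occ` (default 0.9); a bound
site protects its interval extended by `footprint` bp on each side
(default 25, so the 40-bp-spaced operators of a cluster fuse into one
protected block covering only the cluster — the promoter spacer between
operator cluster and I-SceI site is *not* protected, reproducing the
observed loss of co-excised promoter DNA); protected intervals closer than
`merge_gap` (10 bp) merge.  I-SceI sites never protect.

Degradation and shearing: protected intervals always survive and are cut at
uniform-random breakpoints into pieces of 150–300 bp (`frag_len_min/max`);
a protected remainder below 150 bp is emitted flagged rather than discarded
(protein-bound DNA is not lost).  Unprotected stretches are sheared the
same way but each piece survives only with probability
`survival_unprotected` (default 0.002); sub-minimum unprotected remainders
are discarded.

Reads are single-end and cover whole fragments (Ion-Torrent-like variable
length).  Per read, a Bernoulli(`background_rate`, default 0.05) coin picks
the sequence-nonspecific background channel — replicon ∝ copy number ×
length, start uniform on [0, L), length uniform in [150, 300] truncated at
the replicon end — versus the packaging channel, one fragment drawn
uniformly (molar sampling).  Sampling starts uniformly on [0, L) rather
than [0, L − len] keeps the start distribution exactly uniform (unbiased
window-share nulls, exact χ² binning) at the cost of a slight coverage
ramp over the last <300 bp of each replicon.  Substitution errors are
uniform at `error_rate` (0.005); qualities are constant Q30.  All
randomness flows through named child streams ("occupancy", "degradation",
"reads", "errors") of one root seed; a fixed seed reproduces FASTQ/BED
byte-for-byte.

`p_occ`, `survival_unprotected` and `background_rate` are calibration
choices, not measured quantities; they are set so that the simulated
coverage shape matches the qualitative observations (dominant operator
peak, weak plasmid backbone, small helper-plasmid/chromosomal background).

## Coverage and normalization

Depth is the number of primary alignments overlapping each base, computed
by difference-array accumulation (verified against brute-force per-base
membership counting and against `bedtools genomecov`).  Tracks are
normalized as `(depth − m) / m` where `m` is the median per-base coverage
of the chromosome of the same sample, zeros included (excluding zeros would
inflate the baseline; switchable).  Replicate tracks are averaged
elementwise.  Coordinates are 0-based half-open everywhere; strand is
ignored.

## Enrichment statistics

With `N_seg` reads in the segment, `N_rep` on replicon *rep*, and `N_total`
in the sample:

* expected % per 600 bp: `100 · (N_rep / L_rep · 600) / N_total` — the
  share a random 600-bp window of that replicon captures if its reads were
  spread homogeneously along it;
* observed %: `100 · N_seg / N_total`;
* plasmid-relative %: `100 · N_seg / N_rep(target)` (NA when the target has
  no reads);
* fold enrichment: observed % divided by the copy-number-weighted
  homogeneous null `100 · 600 · cn_target / Σ L_i · cn_i` — the share the
  segment would capture if reads were distributed across the whole sample
  exactly as the background channel draws them.  The ratio against the
  realized per-replicon expectation is also reported
  (`fold_vs_replicon`); note that ratio is algebraically capped at
  `L_target / 600` (≈ 8 here) because `N_rep` itself already reflects the
  packaging enrichment, which is why the whole-sample null is the headline
  fold.

Two counting policies: `overlap_any` (≥ 1 bp overlap; the default,
matching region queries on indexed alignments) and `start_in` (start inside
the window).  `start_in` partitions reads over a window tiling and is the
unbiased choice for null comparisons; `overlap_any` overstates a window's
share by roughly mean read length / 600 (~1.4× here), which is a counting
artifact, not enrichment.  Percentages are reported to 3 decimals.

Two statistical subtleties the tests account for:

* **Clustered reads.**  In repressor-off controls only a handful of
  unprotected fragments survive, and all reads from one fragment share its
  interval.  A read-level binomial SE is then far too small; comparisons
  use the Kish effective sample size over distinct truth intervals
  (`stats.kish_effective_n`).
* **Occupancy saturation.**  Under molar (per-fragment) read sampling the
  observed segment share is monotone in `p_occ` only below saturation: near
  full occupancy adjacent bound sites merge into fewer, longer fragments
  and the share plateaus (~82% here) with ~1% jitter.  Monotonicity is
  therefore asserted over the informative range 0–0.6 with common random
  numbers.

## SPR analysis

The 1:1 Langmuir model `dR/dt = ka·C·(Rmax − R) − kd·R`, `K_D = kd/ka`, has
the closed form `R(t) = Req·(1 − e^{−(ka·C + kd)t})` with
`Req = Rmax·C/(C + K_D)` during injection and exponential decay at rate
`kd` during washout; simulation adds Gaussian noise.  Double referencing
subtracts the empty-flow-cell and buffer-blank traces elementwise.
Defaults mirror the experimental protocol: 120-s injections sampled at
0.1 s, 2-fold dilution series, dissociation 80 s (300 s for the
slow-dissociating LexA design).

Kinetic fitting is a global least squares over all curves of a titration in
log-parameter space (positivity by construction), started from a 5×5 grid
(ka 10³–10⁷ M⁻¹s⁻¹, kd 10⁻⁵–10⁻¹ s⁻¹, Rmax 1.2× the largest observed
response); the grid is screened by initial residual and the best three
starts are refined (relative tolerance 1e-10, ≤ 10 000 evaluations each).
K_D dispersion across titrations is reported as mean ± SD of per-titration
fits.  Steady-state affinity fitting of `Req` versus `C` requires ≥ 3
concentrations spanning > 4-fold and refuses flat (saturated/empty)
profiles rather than fitting silently.  Mass-transport limitation, drift
and bulk refractive-index jumps are not modelled.

## Problem sizes and determinism

Standard runs use 100 000 reads and 1000 plasmid molecules per replicate;
null calibrations use 100 seeded runs; SPR noise studies use 200
repetitions of 2 titrations × 8 concentrations (sampled at 0.5 s).  The
pipeline (`run-all`) writes FASTQ, truth BED, raw and normalized bedGraph
tracks, per-replicate and replicate-averaged enrichment TSVs and a log;
with fixed seeds every output byte is reproducible, and every report number
is recomputable from the truth BEDs alone.

## Known limitations

The chromosome is down-scaled (absolute observed percentages are higher
than against a full-length genome); degradation is fragment-level Bernoulli
survival, not per-base exonuclease kinetics; sequencing errors are uniform
substitutions only; the LexA_BT motif is a placeholder; I-SceI cleavage
kinetics, shell geometry and mapper-specific alignment artifacts are out of
scope, so real-data percentages (which also depend on the mapper used) are
expected to differ quantitatively from simulation.
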