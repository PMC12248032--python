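# Methods

`orfish` implements the computational pipeline for mapping the mouse
olfactory receptor (OR) repertoire with combinatorial smFISH: decoding which
OR each sensory neuron (OSN) expresses from multi-round readout images,
decoding single OR transcripts in olfactory-bulb (OB) glomeruli,
reconstructing serial sections into 3D, summarizing the spatial organization
of the repertoire with two scalar indices, transferring scRNAseq-derived
expression onto the imaged coordinates, and cataloguing odor-evoked activity
from Egr1 transcript counts.  Every stage is exercised on synthetic data
with known ground truth; this note records the models, the parameters that
matter, and the choices made where the design was open.

## Combinatorial encoding

Each OR transcript carries a constant-weight binary barcode: a unique set of
4 readout bits out of 15 imaging rounds, giving a capacity of C(15,4) = 1365
codes for the ~1000-gene OR/Taar repertoire.  Constant-weight codes have
even pairwise Hamming distances ≥ 2, so any single dropped or gained bit
falls outside the codebook and is left unassigned rather than misassigned.
Code assignment enumerates the 4-subsets lexicographically, shuffles them
with a seeded generator, and assigns them to receptors in input order; the
scheme is arbitrary but deterministic, which is what downstream
reproducibility needs.  Probe records store layout metadata only (19–20 nt
forward primer, 20 nt RT primer, 15 + 15 nt split readout halves flanking a
30–32 nt target, 19–20 nt reverse primer; each bit tiled 4–10 times per
transcript); nucleotide-level design and genome screening are out of scope.
Blank codes can be reserved for error estimation (`n_blank`), but none are
reserved by default.

## Soma decoding in the epithelium

An OSN expresses one OR at high level, so its soma is bright in exactly the
4 on-bit channels of that OR's code, with the fluorescence texture shared
(hence correlated) across those channels.  The decoder scans overlapping
~2.5 µm cubes (stride half a cube, so somas are never seen only split
across boundaries), computes all C(15,2) = 105 pairwise Pearson
correlations per cube from box-filter moments, and scores all 1365 bit
quadruples by the mean of their 6 internal pair correlations (a single
matrix product against a quadruple-membership matrix).  Cubes whose best
quadruple exceeds the 0.6 correlation threshold contribute their voxels as
candidates; where overlapping cubes disagree, a voxel takes the quadruple
of its best-correlated covering cube.  Candidates are grouped into cells
per quadruple with DBSCAN (radius 1.5 µm, 10-voxel minimum — values chosen
as roughly half a soma radius and a small fraction of a soma volume, and
config-exposed), and each cell is assigned the receptor whose code matches
its quadruple exactly, or left unassigned.  Constant channels inside a cube
yield undefined correlations treated as 0.  Egr1 transcripts are counted as
strict 3D local maxima above threshold inside the cell's voxel set dilated
by one voxel; the default threshold is the channel median plus five robust
standard deviations.

## Transcript decoding in the bulb

Axon terminals carry few transcripts, so the bulb is decoded molecule by
molecule: strict 3D local maxima per readout image (subpixel position from
the 3×3×3 center of mass), then grouping of spots that colocalize within
~160 nm *per axis* (a box, following the per-axis phrasing of the
criterion) in at least 4 distinct bits.  Grouping is greedy by descending
seed-spot brightness — deterministic and biased toward bright, reliable
molecules; when more than 4 bits colocalize, the 4 brightest are kept.  A
per-experiment brightness threshold is the 1-D split minimizing
misclassification between molecules matching targeted vs untargeted codes.
Each segmented glomerulus (masks are an input; segmentation is external) is
assigned its most abundant OR iff the count exceeds 10 and exceeds 10× the
largest count of that OR in any *other* glomerulus of the same section;
"over the other glomeruli" is read as the max (flagged interpretive), and
an OR seen nowhere else counts as 1 in the denominator so any count > 10
passes.  Sub-threshold glomeruli (count > 5) are rescued when another bulb
shows the same OR within 500 µm of the aligned position; rescued entries
are tiered `relaxed` and their position becomes the cross-bulb mean.

## Serial-section alignment

Adjacent sections are aligned on the nuclear channel: ~100 µm tiles (inset
half a tile from the border — border tiles see the empty fill rotation
drags in and bias the angle) are registered by subpixel phase correlation
over a coarse angle grid (±10°, 0.5° steps); the residual rotation is then
fitted from the tile-shift field by least squares against the rotational
flow, iterated three times with 3×MAD outlier rejection, which refines the
angle to the accuracy of the shift estimates (~0.01° in practice).  The
consensus translation is the median tile shift over inliers; automated
outlier rejection replaces the study's manual correction GUI for headless
reproducibility.  Remaining sectioning distortion is corrected by
Gaussian-weighted interpolation of the tile residuals (σ = 75 µm, about one
glomerulus) with a 5σ support cutoff so the correction decays to zero far
from every feature.  Chaining the pairwise transforms composes each section
into the reference frame; z = section index × increment (16–18 µm).
Bilateral stereotypy reflects the right hemisphere about the midsagittal
plane and rigidly registers per-receptor centroids to the left (Kabsch),
reporting matched distances per side; cross-animal consensus registers each
map to the first the same way, with reflection allowed.

## Spatial organization indices

Pairwise spatial overlap between OSN types is the fraction of cells of
either type with a cell of the other type within 200 µm, averaged with
equal weight over sections where both occur.  The phrase "fraction of pairs
of cells within a cutoff" is ambiguous; the cells-with-a-neighbor form is
used because the pair-fraction form vanishes with cell density and cannot
produce near-1 overlap between co-extensive types.  The central-peripheral
(cp) index embeds receptors in 2D with UMAP on 1 − overlap dissimilarity,
orders the main component by the signed difference of graph-geodesic
distances from the two curve endpoints (found by double sweep on a kNN
graph), traces a principal curve by local averaging along that ordering,
and assigns each receptor the normalized arc length of its projection,
scaled to [0, 1].  Receptors disconnected from the main component of the
positive-overlap graph — the "unusual zone" phenotype — are flagged and
excluded from the curve.  Orientation is canonicalized against a reference
(mean radial coordinate) when one is supplied, so 0 is the central end.
The basal-apical (ba) index is the per-receptor mean of
d_basal/(d_basal + d_apical) over its somas; with the synthetic ribbon's
parallel surfaces this is depth/thickness exactly.  Bulb DV coordinates use
150 µm bins, right-closed so a glomerulus on a bin edge belongs to the
lower bin.  Genomic clusters are single-linkage at 100 kb midpoint gaps;
the enhancer test is a two-sided rank-sum of abundance for receptors within
50 kb of an enhancer vs the rest.  Patristic distances come from the newick
branch lengths; set coherence is the resampling rank of the observed
within-set mean distance among size-matched random tip sets.

## Imputation

Type-averaged expression is transferred to each decoded soma or projection
of that type and averaged within 50 µm (epithelium) or 400 µm (bulb) of
each surface point; each gene is divided by the 99th percentile of its
defined surface values and clipped to 1 (the pre-clip values are kept so
the normalization invariant stays checkable).  Leave-one-out projection
prediction rebuilds the surfaces without the held-out receptor (via
sufficient statistics, so it is O(points × genes) per receptor), correlates
each surface point's gene vector with the receptor's own profile, and takes
the arg-max point per region; regions are hemisphere × medial/lateral —
averaging a receptor's "true" position across hemispheres would place it on
the midline where no glomerulus exists.  Genes are z-scored across types
before correlating (switchable) so between-gene baseline differences,
shared by every profile, do not drown the discriminative signal.  Gradient
ranking is the per-gene Pearson r between imputed value and axis
coordinate; gene patterns are clustered by Leiden on a kNN graph of
1 − pattern-correlation and embedded with UMAP, both seeded.

## Egr1 response catalogs

A cell is active when it carries more than 5 Egr1 transcripts (strictly: a
count of exactly 5 is inactive).  An OR's response to a cue is the fraction
of its cells active, averaged as an unweighted mean of per-animal fractions
(pooled-cell fraction is a config option; the study's averaging is not
stated).  Fractions need ≥ 10 pooled cells (binomial SE ≤ 0.16 at worst).
Classes: strong > 0.5, partial > 0.1, else none — both thresholds strict.
Cue comparison uses row-conditional shared fractions |A∩B|/|A| by default
(Jaccard switchable).  The concentration-shift band is the 5th–95th
percentile of replicate-pair differences in 5 equal-count bins of mean
response, linearly interpolated between bin centers; a receptor is flagged
when (high − low) exceeds the upper band.  With tens of pairs per bin the
empirical 95th percentile is noisy, so the realized false-flag rate
fluctuates around the nominal 5% from run to run.  Mother-selective types
require response > 0.05 and > 2× the virgin response.  Differential
expression removes non-female cells (Y-marker expression > 0, or X-marker
below threshold, both config-exposed since the study's marker genes are not
stated), then runs a two-sided rank-sum per gene; the significance flag is
raw p < 0.01 as in the study, with a Benjamini–Hochberg column alongside,
and the reported up-list additionally requires a higher median in the
selected types.  Response mapping weights each cell or glomerulus by its
receptor's responding fraction and bins responding-receptor projections in
200 µm DV/AP intervals, normalized to unit area.

## Synthetic data: what it emulates and what it does not

The generators plant every structure the pipeline assumes: somas bright and
mutually correlated in exactly their 4 on-bit channels; point-like
molecules with one dominant OR per glomerulus plus background; sections
related by rigid motions composed with smooth, bandlimited sinusoidal
distortion whose exact inverse is stored; concentric ring-shaped OR zones
with a per-OR depth offset across an analytic flat-ribbon epithelium (basal
and apical surfaces are parallel planes, so depth truth is exact); a
compact off-ring patch detached by construction (> 200 µm from every ring,
with placement tails truncated) to emulate the unusual zone; OB projection
maps whose DV position is monotone in the cp order and AP position monotone
in the depth offset, mirror-symmetric across hemispheres with isotropic
jitter; graded genes that are monotone in a planted coordinate; and Egr1
counts where responders draw 6 + Poisson(λ_high − 6) — always above the
>5 threshold — and non-responders draw Poisson(λ_low ≤ 1), reproducing the
bimodal count histograms the threshold relies on.

Problem sizes and key defaults: decode sections are 448×448×10 voxels at
0.5 µm lateral / 1 µm axial with 200 somas of radius 3 µm over 50 receptor
types (SNR: amplitude 30 over background 2, noise σ 2).  The voxel grid is
coarser than the instrument's 0.1 µm decoding scale so a full section
decodes in minutes; all signal statistics are defined relative to this
grid, and pixel size is config-exposed.  The atlas uses ring radii evenly
spaced over 150–1400 µm (ring width σ 40 µm): coronal epithelium sections
are millimetre-scale, and the ring system must span several times the
200 µm overlap cutoff, below which the overlap kernel saturates and ring
order is unresolvable in principle.  Depth offsets are uniform in
(0.2, 0.8) with σ = 0.08 across a 60 µm thickness.  Bulbs span
3000×2000×2600 µm with one medial and one lateral glomerulus per
hemisphere per OR, 30 µm jitter, dominant counts of ~30 transcripts.
Expression matrices grade 30% of genes, split between the cp and ba axes.

What passing these tests shows is that each stage recovers exactly the
structure it models, at realistic geometry and counting noise.  What they
do not show: robustness to optical effects absent from the generators —
point-spread blur, autofluorescence, bleed-through, illumination gradients,
segmentation errors in the glomerulus masks — nor to biological departures
such as multi-OR-expressing immature OSNs.  Real-data performance claims
(e.g. 75–77% transgenic detection efficiency) are properties of tissue and
instrument, not reproducible here; the synthetic analogs are deliberately
property-based.

## Numerical choices and degenerate inputs

Half-open, 0-based intervals and voxel indices throughout; physical
coordinates are voxel center × pixel size.  Cube box means come from
`uniform_filter` sampled at cube centers (exact for odd cube sizes; the
overlapping stride absorbs the half-voxel offset of even sizes).
Correlations are clipped to [−1, 1]; constant channels give r = 0 and a
flag.  The brightness split threshold falls midway between the bounding
order statistics.  Ties in greedy colocalization and in sorting break by
index, making every stage order-independent.  Degenerate cases raise or
warn rather than guess: over-capacity codebooks, cubes larger than the
image, all-equal overlap matrices, single-population brightness fits,
fewer than 2 bulbs for consensus, fewer than 3 shared receptors for map
registration, empty selected groups in differential expression.

## Known limitations

The cube stride trades boundary robustness for ~4× compute; adjacent somas
of different ORs closer than a cube can contaminate each other's
correlations.  The cp index is defined up to reversal without an external
reference, and its arc-length spacing (not just order) inherits embedding
noise.  The LOO projection error cannot beat the averaging radius, because
excluding a receptor leaves a hole in the surface precisely at its own
position.  The replicate band estimator is noisy at few replicate pairs.
Leiden cluster *labels* are seed-stable only up to relabeling; tests
compare partitions, not label values.
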