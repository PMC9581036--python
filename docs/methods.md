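# Methods

## The acquisition model

smartscan organizes image acquisition as two nested scans. The *primary*
scan covers a large stage region quickly — coarse lateral sampling (camera
binning factor `k`), few z-slices, usually one channel — either as one
contiguous tiled map or as independent blocks. Tiles are maximum-intensity
projected per channel and assembled side by side (tile grid positions refer
to tile centers; tiles abut with zero overlap, and no overlap registration
is attempted). A detection workflow turns the assembled map(s) into a list
of stage-coordinate targets. The *secondary* scan then revisits only those
targets at full resolution: one stack per target for fixed samples, a
fixed-length time-lapse of `L` frames for live ones.

Four state machines cover the mode matrix:

* **tiled_fixed** — one primary map, one detection call, optional user
  review via a montage and a plain-text selection file (one accepted cell
  index per line; an absent file accepts everything), deduplication, an
  optional top-score cap, then one secondary pass. Review defaults on.
* **block_fixed** — blocks analyzed sequentially, per-block targets tagged
  and accumulated, a *single* secondary scan after the last block. Review
  defaults off (typically too many targets to inspect).
* **tiled_live** — periodic primary maps; the detector runs only once the
  3-frame queue is full (frames 0 and 1 are never analyzed). On a hit the
  highest-scoring target triggers an immediate burst of `L` secondary
  frames; the engine is *blind* during the burst, the queue is flushed
  afterwards, and the run stops after `max_events` bursts or the primary
  frame budget.
* **block_live** — round-robin over blocks, each with its own 3-frame
  queue; a hit triggers the burst before the next block's frame, and only
  the triggering block's queue is flushed.

Design choices where the behaviour was genuinely open: simultaneous live
detections acquire only the highest-scoring one (the system is optimized
for fast imaging of single targets; the other event is acquired only if
still detectable later); the live queue is flushed after a burst because
the pre-burst frames are stale after the dwell and would create spurious
difference signal; the fixed-mode cap keeps top scores with ties broken by
detection order; "centered on the target" means the stage is repositioned
so the target sits at the field-of-view center; block order in block-live
is plain round-robin (a fair schedule, none being otherwise mandated).
Frame pacing is logical (frame indices, not wall clock), which makes runs
deterministic and replayable; how much sample time elapses during a burst
is configurable (`secondary_dwell_frames`, default 0).

## Image operators

All rank filters (median, outlier removal) use a pixelated disk
neighborhood *clipped to the image bounds* at the edges — no reflected or
constant padding — implemented as a sorted stack of shifted views so a
brute-force per-pixel oracle can verify them bit-exactly. Outlier removal
follows the classic rule: a pixel is replaced by its neighborhood median
only when it exceeds it by more than a threshold (bright mode; dark is
symmetric), which makes the operator idempotent on impulse noise.

Global thresholds are either fixed or Otsu on a 256-bin histogram
(between-class variance maximization; when the histogram has an empty gap
between modes the optimum is a tied plateau and any maximizer is accepted).

The LoG band-pass is the negated Laplacian of the Gaussian-smoothed image:
with this sign convention **dark** blobs of diameter ≈ 2√2·σ produce local
*minima* of the response and bright blobs produce maxima. The mitosis
workflow therefore finds tubulin-dark nuclei as minima of the response,
while the FISH and micropattern workflows count *bright* blobs (spots,
DNA-stained nuclei) as minima of the negated response. "Significant"
minima are defined by topographic prominence (dynamics ≥ h, computed with
h-minima morphological reconstruction), not raw depth, so counts are
invariant to any constant intensity offset; the global minimum is always
significant, constant images have none, and candidates are
non-maximum-suppressed at a minimum mutual distance with deterministic
(row, col) tie-breaks.

Particle analysis uses 8-connected components with area gates and a
circularity gate 4πA/P², where P is the Crofton perimeter estimate (less
raster bias than edge counting; values may slightly exceed 1 for small
disks). Centroids are pixel means.

Pixel coordinates are 0-based (row, col) with y increasing downward; stage
axes are aligned with pixel axes. Real microscopes may flip axes — that
mapping is a config concern of a hardware bridge and is untested against
hardware.

## Detection workflow parameters

None of the workflows' numeric parameters are universal constants; they are
exposed per workflow with defaults tuned once against the standard
simulator fixtures (all lengths in pixels of the assembled primary map,
intensities in camera counts):

* **metaphase**: median radius 2; outlier radius 8 (larger than the
  condensed-core radius, so the local median reflects background);
  outlier threshold 45 (between the interphase amplitude ≈ 38 and the
  condensed amplitude ≈ 110 on 8-bit fixtures); particle area ≥ 12 px.
* **fish**: nucleus gates area ∈ [40, 800] px (fixture override
  [60, 1200]), circularity ≥ 0.6; watershed seed separation 8 px; spot LoG
  σ 1.5 px (override 1.2 = spot σ at the fixture sampling), spot
  prominence 10, spot NMS 3 px.
* **micropattern**: pattern mask = Otsu + closing (radius 2) with area
  gates [30, 5000] px; box margin 3 px; nucleus LoG σ 1.5 px —
  deliberately *under* the nucleus scale (σ ≈ 2.5 px) so two nuclei one
  diameter apart remain separate minima — prominence 2, NMS 3 px.
* **mitosis_live**: difference = newer − older clamped at zero (tubulin
  invasion *raises* intensity at NEB); median radius 2; Otsu threshold on
  the difference with a fixed-value override; nucleus-like gates area ∈
  [40, 2000] px, circularity ≥ 0.5, and a mean-difference floor of 15
  counts (the NEB contrast is large; noise-level changes are not events);
  nucleus validation via LoG σ 3 px, prominence 2 (a dark disk's band-pass
  response is shallow, ≈ 3 counts for the fixture's 45-count contrast).
  The optional temporal-persistence mode additionally requires overlap
  with a candidate from the previous frame pair (this uses the third
  queued frame); it is off by default and is a generic stand-in for
  application-specific false-positive suppression on highly motile
  samples.

The FISH signature list is ordered: the first signature whose per-channel
predicates (==, ≥, ≤) all hold labels the nucleus, so listing order is
user priority and several phenotypes can be collected in one run.

## The virtual microscope

The simulator renders 2D Gaussian objects (nuclei, FISH spots) and
rasterized shapes (micropatterns as disk/cross/H/Y at uniform intensity;
live cells as bright cytoplasm disks with dark nuclear disks) blurred by a
Gaussian PSF, with exponential amplitude attenuation per µm of defocus,
optional Poisson shot noise and Gaussian read noise, clamped to the 8- or
16-bit range. A scheduled NEB event fills a nucleus's dark disk with
bright tubulin-level signal from its onset frame; live objects undergo
Brownian motion (σ µm/frame). Primary-resolution tiles are computed as the
exact k×k block mean of the full-resolution render — camera binning — so
the two resolution modes are mutually consistent by construction.

Everything derives from a single spec seed: object placement (rejection
sampling with minimum separations; impossible packings fail after bounded
retries), phenotype assignment, motion (cached per-frame cumulative steps)
and noise (a counter-based RNG keyed on seed, frame, channel, z and stage
position, so repeated renders of the same view are identical and recorded
TIFF payloads are byte-identical across runs).

Deliberate simplifications: no 3D PSF (detectors consume max projections,
so z realism buys nothing), no photobleaching, drift, flat-field error or
optical aberrations, and the condensed-nucleus count is the *rounded
fraction* of the population rather than a binomial draw, so the standard
fixtures have a known, fixed number of events. Consequently, passing
fixtures demonstrates the correctness of the pipeline logic and the
operators on unambiguous, well-separated objects — not detector
performance on real, crowded, variable samples.

Fixture conditions (chosen once as typical of the corresponding bench
settings): metaphase — 200 nuclei on 400×400 µm, 2.5% condensed at 3×
intensity, 10×10 map of 40 µm tiles at 2× binning, 3 z-slices; fish — 50
nuclei on 300×300 µm, 3 FISH channels, 20% abnormal (1, 0, 1) signature;
micropattern — a 12×12 block at 30 µm pitch with occupancy probabilities
{0: 0.55, 1: 0.15, 2: 0.30} (≈ 15% singles, the frequency seen in
practice); mitosis_live — 3 cells on 128×128 µm, tubulin 60 counts,
nuclear dark level 15, NEB fill 90, Brownian σ 0.3 µm/frame.

## Protocol and replay

The client–server dialect is a documented, versioned text protocol: one
LF-terminated line of space-separated `/key:value` fields, commands
`startscan`, `stopscan`, `setposition`, `startcycle`, `stopcycle`,
notification `/inf:scanfinished`, positions in µm as decimal text (a
hardware bridge must check its platform's unit convention). Unknown
commands pass through for forward compatibility; since fields are
space-separated, keys and values must not contain whitespace. Transport is
any line stream — the simulator server is driven in-process through the
same interface, so the contract is tested without sockets.

Images are exchanged through a folder under the name pattern
`{exp}_t{T:04d}_b{B:03d}_r{R:02d}_c{C:02d}_ch{CH:02d}_z{Z:03d}.tif`.
The collector polls until every expected file exists with a size stable
across two polls (robust on network shares, where change notifications are
unreliable); non-conforming files are ignored. Offline replay serves a
recorded folder in time order through the same backend interface the live
simulator implements, so an engine run and its replay produce identical
acquisition logs (timestamps aside) — secondary images are not part of the
primary record and are served blank, which does not affect control flow.

## Numerical and degenerate-input conventions

Target deduplication is greedy by descending score (ties by input order)
on lateral (x, y) stage distance — z is a focus coordinate and does not
distinguish objects; the result is order-independent for distinct scores.
Focus interpolation across a region is bilinear from the four corner z
values. Target CSVs store µm to 6 decimals and scores in full float
precision, so save/load round trips are lossless. Empty masks, blank maps,
all-zero difference frames and empty target lists all propagate to empty
results rather than errors; a detector asked for a missing channel, a
malformed CSV line, a selection index out of range, or a position outside
the grid footprint raise named errors.

## Test problem sizes

The suite and the acceptance script run entirely on generated data at
desk scale: 400×400 px primary maps (metaphase, micropattern), 600×600
(fish), 128×128 (live), 50 live runs of ≤ 25 frames for the state-machine
contract checks, 100 random ≤ 16×16 images per operator-oracle comparison
and 1,000 random instances for protocol round trips. These sizes keep the
whole suite under a minute of compute while leaving every contract
exercised end to end; the biological results of a real experiment (event
yields over hours of wall-clock imaging, false-positive rates on motile
primary cultures, sub-hour wide-field survey times) depend on samples and
hardware and are out of scope by design.
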