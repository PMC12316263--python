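# Methods

## The problem and the approach

Visual QC of pipeline outputs at database scale has three requirements:
every output is looked at; the look is cheap (one image, fast to load,
identical layout across a team); and the verdicts are durable, mergeable and
analysable. `scanqc` decomposes this into triage (admit raw data), render
(one deterministic PNG per output), store (a CSV audit table), review (a
cycling three-state rating loop), and agreement (how consistent the verdicts
are, across humans or against an automated classifier).

## Triage rules

Diffusion scans are admitted only when (1) both bval and bvec sidecars are
present and (2) the scan has at least `MIN_DWI_VOLUMES = 6` volumes. Rule 1
is checked before rule 2, so a short scan that also lacks sidecars is coded
`MISSING_BVAL_BVEC`. A reverse phase-encoding (RPE) scan — detected from the
BIDS `dir-` entity or an explicit inventory flag, never from headers — is
exempt from rule 2 when a *companion* exists: a DWI of the same subject and
session that itself passes both rules with ≥ 6 volumes. Companionship is
evaluated live against the inventory passed in, so removing the companion
removes the exemption. An RPE scan with ≥ 6 volumes is admitted on its own
merit; no upper volume bound is imposed on the RPE class. Structural T1w
scans are always admitted. Triage never raises on content: its output is an
exhaustive, disjoint partition with a rule code and human-readable reason
per exclusion, which is the machine-readable substitute for going back to
the data provider.

## Rendering

All volumes are reoriented to canonical RAS with `nibabel` before slicing,
so axis permutations of the stored array (with matching affine) cannot
change the raster. Display intensity maps the [p1, p99] percentile window
linearly to [0, 1] — robust to hot voxels; a degenerate (constant) window
renders as background. Slice positions default to fractions (0.3, 0.5, 0.7)
of each dimension: mid-volume ± 20 % keeps tissue in frame for typical head
fields of view, and the fractions are configurable per recipe. Each slice is
nearest-neighbour resampled to a fixed 160-px panel, giving a fixed canvas
per layout regardless of acquisition matrix.

Overlays blend per pixel as `(1−α)·gray + α·palette(label)` for non-zero
labels; label 0 is background and is never drawn. The palette is a fixed
256-entry table indexed by label id mod 256, built from golden-ratio hue
stepping — a pure function of the id, hence stable across runs and machines
without hashing. Side-by-side comparisons share the intensity window of the
*first* (reference, e.g. uncorrected) volume so brightness differences are
real signal. Scalar-map grids show three axial slices per map with a
per-map colorbar spanning that map's own display window. Multipage
documents flatten by vertical stacking, narrower pages centred on
background; height is exactly additive.

PNG output goes through Pillow with no ancillary metadata chunks and the
embedded bitmap font for annotation text, making re-renders byte-identical
— the determinism contract the tests and the acceptance script check. The
Pillow/numpy path was chosen over matplotlib precisely because determinism
is then a property of the code rather than of a rendering backend's
versioned defaults. 4D raw DWI previews show volume 0 (conventionally the
b=0 acquisition) with the volume count printed in the annotation band.

## Audit store

One CSV per (dataset, pipeline), header
`dataset,pipeline,subject,session,acquisition,run,item,qc_status,user,timestamp,reason`,
UTF-8, RFC-4180 quoting, rows sorted by the full identifier key. Every
mutation rewrites the file to a temporary name in the same directory,
fsyncs, and renames into place — readers never observe a torn file, and a
killed process loses at most the mutation in flight. Timestamps are UTC
ISO-8601 so "latest wins" is well-defined across machines; merge resolves
full-key collisions by timestamp with argument order as the tie-break,
which makes aggregation associative. New rows enter only through table
initialization (everything "yes") or automatic-failure ingestion (status
"no", user "auto"); human verdicts may overwrite auto rows by ordinary
recency, with provenance kept in the user column.

## Review loop

The session is a pure state machine (items sorted lexicographically —
identical review order for every team member — cursor, viewed-set, montage
mode) over preloaded PNG bytes; any front end drives it through
`navigate` / `set_status` / `montage_tick`. Navigation clamps at the ends
rather than wrapping, which keeps "documents left to view" well-defined:
remaining = total − distinct viewed, counting *viewed* rather than judged
because every item starts "yes" and viewing is the act of judgment. Montage
periods are 1 s (slow) and 1/3 s (fast) per image, configurable; recording
a verdict pauses the montage. Every verdict is persisted before the next
event is accepted.

## Agreement statistics

Fleiss' kappa is computed exactly as stated in the README formulas. The
all-one-category panel has `p_e = 1` and an undefined ratio; it is reported
as κ = 1 with a `degenerate` flag, since the raters do agree perfectly.
Landis–Koch banding uses the conventional closed edges (fair 0.21–0.4,
moderate 0.41–0.6, substantial 0.61–0.8, almost perfect > 0.8); values
falling in the two-decimal gaps between bands join the band below, and
everything under 0.21 is reported as a single "slight or worse" bottom band
rather than distinguishing slight from poor. Kappa is reported to 3
decimals. For comparison against a binary classifier, three-state ratings
are binarized under an explicit maybe-policy (`as_pass` default — a
"maybe" output is usable pending the analyst's judgment — with `as_reject`
and `drop` available); kappa itself always uses the full three categories.

## Synthetic fixtures

Phantoms are geometric, not anatomical: an ellipsoidal "head" with
`n_shells` concentric intensity bands (noise-free phantoms have exactly
`n_shells + 1` distinct values, an exact construction oracle), disjoint
spheres for label maps, and 4D stacks with FSL-dialect sidecars whose first
volume is b=0. Rating panels draw a latent category per item from a base
distribution and have each rater report it with probability `a`
(else err uniformly), so `a = 1/k` is the independence null (κ ≈ 0),
`a = 1` forces unanimity (κ = 1), and mean κ increases monotonically in
`a`. Default volume shape is 64³ (tests use 16–32³) to keep the full suite
in seconds. What passing tests show is that the *contracts* hold —
slicing geometry, blending arithmetic, partition laws, persistence,
statistics; they say nothing about whether a human can recognise a real
registration failure in the rendered image, which is inherently outside a
synthetic fixture's reach.

## Problem sizes in the verification scripts

The acceptance script and suite use: the 1560-scan contingency counts as
printed; 500 random panels for oracle equivalence at 1e−12; N = 2000 items
for the chance null (|κ| < 0.05 tolerance is the Monte-Carlo band at that
N); 100 replicates of 200-item panels per agreement level for monotone
recovery; 5–6-subject fixture trees for the failure-mask experiments; and
32³ phantoms for determinism checks.

## Known limitations

- No surface rendering: surface-based QC images from external tools are
  consumed via page flattening or PNG passthrough, not regenerated.
- No DICOM, no phase-encoding inference from headers, no gradient-table
  sanity checks beyond shape and length consistency.
- The store keeps last-write state only — no per-row edit history.
- No bootstrap confidence intervals for kappa and no weighted variants;
  the three nominal categories are treated as unordered.
- The terminal review front end is intentionally minimal; the session API
  is the stable surface for richer front ends.
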