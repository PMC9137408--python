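# Methods

## Problem and model

Membrane-filtration enrichment of peripheral blood leaves a mixture of
rare tumor cells and abundant leukocytes on a perforated membrane.  After
immunofluorescence staining (DAPI nucleus / STEAM tumor cytoplasm / CD45
leukocyte cytoplasm), tumor cells are distinguished morphologically by a
**high karyoplasmic ratio**: malignant nuclei grow faster than their
cells, so the nucleus occupies most of the cell footprint
(KR ≈ 0.77–0.88 in tumor cells vs. ≈ 0.40–0.53 in leukocytes).  The
pipeline encodes the visual counting procedure as deterministic image
operations; there is no training step and no learned component.

The decision rule per segmented cell, with cell area defined as the union
of the three binarized channel masks, is

```
CTC  ⇔  KR > K  ∧  Red_prop < R  ∧  green target present
```

with strict inequalities.  The third conjunct is a deliberate design
choice: without it, a completely unstained nucleus (no green, no red)
would score KR = 1 and be called a CTC, although nothing marks it as a
tumor cell.  It can be disabled (`require_green=False`) to recover the
literal two-threshold rule.

## Parameters

| parameter | default | units | meaning / rationale |
|---|---|---|---|
| `h1`, `w1` | 46 | px | lower size gate, slightly below the ~56 px filter-hole diameter; excludes hole-scale artifacts and debris |
| `h2`, `w2` | 200 | px | upper gate, slightly above the 180 px hole spacing; excludes large contamination |
| `expand_factor` | 3 | — | per-axis enlargement of the tight nucleus box; makes the nucleus ~9% of the window, which places its gray levels inside the 80–95% histogram band |
| `seed_window` | 11 | px | central square from which blue seeds are drawn |
| `seed_lo`, `seed_hi` | 0.80, 0.95 | fraction | closed percentile band (nearest-rank) of window gray values admissible as seeds |
| `p` | 0.2 | — | growth similarity factor; see below |
| `kr_threshold` (K) | 0.70 | fraction | KR cut separating high-KR (tumor-like) from low-KR cells |
| `red_prop_threshold` (R) | 0.35 | fraction | CD45 area proportion above which a cell is treated as carrying the leukocyte antigen |
| `morph_radius` | 1 | px | 3×3 structuring element for the opening/closing cleanup |

`p` has no published value; 0.2 is chosen so that a flat stained region
(relative intensity fluctuations well under 20% at typical IF
signal-to-noise) grows as one body while the ~10× darker membrane
background never joins.  Growth is monotone in `p`, so the choice trades
under- vs. over-segmentation transparently.

## Numerical choices

- **Otsu**: exhaustive search over the 256 possible 8-bit cut points,
  foreground = gray > t; ties take the smallest maximizing threshold, so
  output is deterministic.  A constant raster has no valid split and
  yields an all-background mask.
- **Connectivity** is 8-connected throughout (components and growth).
- **Box expansion** centers on the tight box; an odd pixel remainder goes
  to the bottom/right; boxes are clipped at image borders, and
  border-touching nuclei are processed normally.
- **Percentiles** are nearest-rank over all window pixels; a constant
  window degenerates to P80 = P95 and the whole seed region qualifies.
- **Background modes**: the most frequent gray value, ties resolved to the
  lowest (background is dark in IF).  Spreads are population standard
  deviations of raw gray values.
- **Growth conditions** are evaluated at the already-accepted center
  point whose 8-neighborhood is examined (classic seeded growth); the
  fixed point is order-independent, implemented as synchronous frontier
  sweeps and verified against a queue-based breadth-first oracle.
- **Channel presence**: a green/red channel is declared empty when the
  mean gray under the nucleus mask differs from both the global and the
  local background mode by less than one corresponding standard
  deviation; a zero difference also counts as empty when the deviation is
  zero (degenerate constant channel).  Presence can be triggered by
  structures other than stain — e.g. a filter hole under the cell pulls
  the mean below background — but the subsequent growth then finds no
  bright target, the mask stays (near) empty, and classification is
  unaffected.  This hole interference is a real property of the assay
  images, not an artifact of the implementation.
- **Empty nucleus mask** after growth/cleanup is a measurement error; the
  candidate is dropped with a logged warning rather than propagated.

## Synthetic scenes

The generator renders what the pipeline needs to see, not cell biology:
a uniform membrane background (gray 12) with darker filter holes
(gray 2, 56 px diameter, 180 px square lattice), cells as a bright
nucleus disc (blue, gray 180–220) inside a concentric cytoplasm disc
(green for tumor cells, red for leukocytes, gray 140–180), i.i.d.
Gaussian noise (default σ = 3) clipped to 8 bits.  Planted KR is the
pixel-count ratio of the rendered discs, logged per cell in the truth
table together with the tight box and true label.

Populations: tumor cells target KR ≈ 0.75–0.89 (nucleus radius
25–32 px), "small CTCs" sit just above the lower size gate
(cell diameter ≤ 51 px ≈ 16 µm at the default ~3.1 px/µm scale) with
near-unity KR, leukocytes target KR ≈ 0.39–0.52, and occasional debris
blobs exceed the upper size gate.  The default population mix gives the
~24% CTC prevalence of a per-cell clinical validation set.  Leukocyte
nuclei are drawn at ≥ 47 px diameter — above the lower gate — because the
pipeline can only be exercised on cells that reach the classifier; real
leukocyte nuclei at this scale straddle the gate.

Default scenes are 720×960 with 10 cells; cells are placed so that no
neighbor's cytoplasm enters another cell's expanded analysis window.
What passing tests therefore show: the implementation recovers exactly
what it planted under disc geometry, uniform staining, moderate noise and
non-overlapping cells.  What they do not show: robustness to uneven
illumination, textured cytoplasm, touching or overlapping cells, focus
drift, or antibody-cocktail batch effects — the failure modes that
dominate real clinical images.  Clinical-scale performance figures are
reproduced only as metric arithmetic on a published per-cell tally, not
re-measured from images.

## Evaluation

Scoring is per cell.  Detections are paired with truth cells of the same
field of view by **mutual box-center containment** (each box contains the
other's center), nearest centers first, one-to-one.  Unmatched truth
cells count as predicted non-CTC; an unmatched predicted CTC is a false
positive; an unmatched predicted non-CTC carries no information.  The
five metrics are derived from the TP/FP/TN/FN tally; any metric with a
zero denominator is reported as undefined, never silently zero.

## Known limitations

- Touching nuclei merge into one candidate (no watershed splitting).
- The seed band assumes the nucleus occupies roughly 5–20% of its
  analysis window; grossly non-elliptical nuclei or crowded windows can
  starve seed selection.
- JPEG inputs are accepted but lossy; all internal fixtures and
  round-trip guarantees use PNG.
- No illumination correction, stitching, or µm-calibrated measurements;
  the µm-per-pixel scale only parameterizes the synthetic generator.
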