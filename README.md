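# filagraph

Morphometric analysis of filament networks in fluorescence micrographs:
trace every individual actin filament in a 2-D image (or a max-projected
confocal stack) and measure its length, producing per-filament tables,
length-frequency distributions and count-weighted summary statistics.
Built for quantifying cytoskeletal remodelling — e.g. comparing filament
length distributions between treated and control cells — and validated
end-to-end on synthetic filament networks with exact ground truth.

## Method

The pipeline runs four estimation–inference steps:

1. **Enhancement.** The image *I* is correlated with a bank of artificial
   filament templates *K(θ, ℓ, σ, κ)* — constant-curvature ridges with
   Gaussian cross-section, enumerated over rotation θ, length ℓ, width σ
   and signed curvature κ, each mean-subtracted and L2-normalised.  The
   filament-likelihood image is

   L(x) = N[ maxₖ (I ⋆ Kₖ)(x) ]₊ · N[ I(x) ],

   the pixelwise product of the min-max-normalised best template response
   (clamped at 0) and the normalised intensity: both ridge structure and
   brightness must be present, which suppresses diffuse background
   fluorescence and noise spikes.  The winning template's rotation gives a
   local orientation map.
2. **Binary clustering.** L is split into filament and non-filament pixels
   by two-class 1-D clustering (centroids initialised at min and max,
   iterated to convergence — equivalently a threshold at the midpoint of
   the converged centroids), then small components are removed.
3. **Thinning.** The mask is reduced to unit-width centerlines by
   topology-preserving parallel thinning; short spur branches are pruned.
4. **Disambiguation & measurement.** The skeleton becomes a graph of
   endpoints, junction knots and pixel chains.  Crossings and bifurcations
   are resolved by geometric continuity: branch ends at each knot are
   paired by a minimum-total-cost matching (tangent turn angle plus joint
   line/arc-fit residuals), fused tip-to-tip chains are split at sharp
   interior corners, shallow crossings are re-joined by bridging along the
   skeleton, and arc-consistent fragments are merged.  Each filament's
   length is the Euclidean arc length of its smoothed centerline; lengths
   convert to micrometres when the pixel size is known.

A built-in generator renders synthetic networks — constant-curvature arcs
with Gaussian cross-section, Gaussian-distributed lengths, pixelwise-max
compositing and additive noise — with exact ground truth, and a validation
harness scores the full pipeline against it (filament-count error and
matched-length RMSE).  See `docs/methods.md` for models, parameters and
limitations.

## Worked example

Simulate one 128×128 image with five filaments, trace it, and report
lengths at 0.15 µm/px:

```bash
filagraph simulate --out sim --seed 11 --n-filaments 5
filagraph trace sim/image_000.tif --out traced --pixel-size-um 0.15
cat traced/filaments.csv
```

```
id,length_px,n_pixels,mean_orientation_rad,closed,length_um
0,71.6255,68,1.2942,False,10.7438
1,61.8873,56,2.821,False,9.2831
2,53.3925,47,0.529,False,8.0089
3,62.6412,53,2.3503,False,9.3962
4,47.3341,48,1.4575,False,7.1001
```

All five simulated filaments are recovered; the ground truth written next
to the image (`sim/image_000_truth.json`) lists true lengths of 10.46,
9.25, 8.05, 9.47 and 7.15 µm — each traced length lands within ~0.3 µm.
`traced/summary.json` holds the count-weighted mean length
(8.91 ± 0.63 µm here) and `traced/histogram.csv` the binned length
distribution.  For real data, `filagraph trace image.tif --out results
--project` first max-projects a multi-page TIFF z-stack; library users
call `filagraph.trace_image` / `filagraph.length_distribution` /
`filagraph.compare_groups` directly.

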