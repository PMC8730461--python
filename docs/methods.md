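# Methods

## Model and scope

`bsp3d` treats a body scan as a watertight triangle surface bounding a
uniform-density solid per segment. All BSPs are then *measurements* of
that solid, not model fits:

- **Volume, COM, inertia** come from exact polyhedral integration
  (origin-anchored signed tetrahedra with the canonical simplex moment
  formulas). The COM is the volumetric centroid of the enclosed solid —
  deliberately *not* a vertex average, which over-weights densely
  triangulated regions. The inertia tensor is referenced to the COM and
  read out on the segment's anteroposterior / mediolateral / longitudinal
  axes.
- **Longitudinal length** is found by casting a ray from the COM along the
  segment's long axis in both directions and taking the farthest surface
  intersection on each side; for concave segments the farthest hit (not
  the first) defines the endpoint. **pCOM** is the orthogonal projection
  of the COM onto the endpoint–endpoint line, as a percentage of length
  from the proximal endpoint.
- **Segmentation** replaces manual mesh editing with boundary-plane cuts:
  straddling triangles are split by edge–plane interpolation and each
  boundary loop is capped with a fan from the loop centroid. Body
  cross-sections are near-convex, which is what makes the centroid fan
  valid; heavily folded geometry would need a general polygon
  triangulator and is out of scope.

Assumptions: uniform density within a segment (a spatially varying density
field is compatible with the integration scheme but not implemented);
planar segment boundaries; a standing, roughly axis-aligned posture so
that the global longitudinal axis is a sensible long axis for every
segment except the feet.

## Coordinate conventions

The canonical frame is right-handed with ap = +x, ml = +y, long = +z
(superior), satisfying ml × long = ap. Every segment uses the global frame
except the feet, whose longitudinal axis is re-aligned to the dominant
horizontal (heel→toe) extent of the foot mesh, with the former vertical
axis becoming the foot's anteroposterior axis; ties in horizontal extent
break toward global ap with a warning.

Proximal endpoints: superior end for head, trunk segments, thigh, shank,
and the arm chain (shoulder/elbow/wrist end in a standing scan); the heel
(−long end) for the foot. The table is overridable per call.

## Units and parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| mesh coordinates | cm | — | must be declared explicitly (`cm`/`m`/`mm`); autodetection is refused because a silent m↔mm slip scales inertia by 10⁵ |
| density | kg/m³ | per-segment literature table | head 1110, torso 920, abdomen/pelvis 1010, thigh 1050, shank 1090, foot 1100, arm 1070, forearm 1130, hand 1160 — external cadaver/CT-derived constants, user-overridable |
| uniform density mode | kg/m³ | 1000 | density of water; the assumption-free fallback |
| inertia | kg·cm² | — | matches the cm/kg convention of the outputs |
| STL vertex merge | cm | 1e−6 | STL stores facet soup; merging restores connectivity |
| cut plane tolerance | cm | 1e−9 | vertices within this distance count as on-plane |

Meshes with negative signed volume (inward winding, common across capture
tools) are flipped automatically with a logged warning rather than
rejected.

## Comparison estimators

**ECM.** Each segment is a proximal→distal stack of elliptical cylinders
(a = ml semi-axis from the frontal width, b = ap semi-axis from the
sagittal depth, height h). Per slice: V = πabh, I_long = m(a²+b²)/4,
I_ml = m(3b²+h²)/12, I_ap = m(3a²+h²)/12; composites by mass-weighted COM
and the parallel-axis theorem along the stack axis. Slice thickness is a
user choice (profiles come in as CSV tables, standing in for a photograph
digitizing step); a single circular slice is algebraically identical to a
solid cylinder, which the tests exploit.

**Regression.** Segment parameter = B₀ + B₁·W + B₂·H (W body mass kg, H
stature cm). The male segment-mass triples are the classic
photogrammetric cadaver-population coefficients; inputs outside the
development population (W ∉ (30,150), H ∉ (130,210)) trigger a warning.
Female masses ship as a documented proportional model (adjusted female
mass fractions, B₀ = B₂ = 0) because sex-specific triples with verifiable
provenance were not available; moment-of-inertia triples are likewise not
shipped — requesting them raises an explicit not-available error unless a
user coefficient CSV supplies them. Population mean length/pCOM tables
back the quantities the regressions do not model; blank entries raise
rather than default.

## Reliability statistics

CV is sample SD / mean × 100 (the normalized-variability convention; note
some write-ups print the inverted ratio while reporting SD/mean values).
ICC comes from the two-way subjects × repetitions decomposition:
ICC(2,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) (absolute agreement,
the default) and ICC(3,1) = (MSR−MSE)/(MSR+(k−1)MSE) (consistency); the
variant is always recorded. An all-equal matrix is defined as ICC = 1 with
a warning. Bland–Altman limits of agreement are bias ± 1.96·SD of the
paired differences, exactly. The repeated-measures ANOVA F is the
conditions mean square over the subject × condition residual, unadjusted
— sphericity tests, epsilon corrections and post-hoc machinery are out of
scope. Label cut-offs: CV >15 not acceptable / 15–10 acceptable / 10–5
good / <5 very good; ICC <0.5 poor / 0.5–0.75 moderate / 0.75–0.9 good /
>0.9 excellent.

## Synthetic phantom

The generator emulates the *geometry* of a segmented scan, not the sensor:
closed primitive meshes (cylinder, elliptical cylinder, frustum,
ellipsoid, box) with vertices exactly on the analytic surface, assembled
into a 16-segment humanoid (elliptical-cylinder trunk column, ellipsoid
head, frustum limbs hanging vertically beside the trunk, box feet pointing
anteriorly). Dimensions were chosen once to give an adult-male-scale body
of ≈73 kg at the literature densities. Adjacent primitives share exact
planar interfaces; the emitted scheme planes sit 1e−3 cm off each
interface so cut planes never coincide with coplanar cap facets (which
would strand open slivers) — the volume misattribution this causes is
below 10⁻⁴ relative, far inside every tolerance used. The optional noise
model displaces vertices along vertex normals by a seeded Gaussian; it
captures surface roughness only, not occlusion, sway or warm-up drift of a
real depth sensor. Passing phantom tests therefore demonstrates the
correctness of the geometry pipeline, not robustness to real scan
artifacts.

Analytic truths: cylinder V = πr²L, I_trans = m(3r²+L²)/12,
I_axial = mr²/2; ellipsoid V = 4πabc/3, I = m(b²+c²)/5 (cyclic); box
I = m(w²+d²)/12 (cyclic); frustum by exact polynomial integration of the
linear radius profile. The reference validation cylinder (r = 4.1 cm,
L = 94.0 cm, ρ = 1000 kg/m³) gives 4964 cm³, 3676 kg·cm² transverse and
42 kg·cm² axial; the length check uses a separate 94.1 cm cylinder, which
is internally inconsistent with the former set by ~0.1% and is therefore
kept as its own setup.

## Numerical choices and problem sizes

- Mesh resolutions: validation cylinders at 512 circumferential × 200
  axial divisions (inscribed-polygon volume deficit ≈ 2.5×10⁻⁵); the
  end-to-end phantom check runs at 256 divisions, where recovery errors
  are ≲0.2% for mass/length/pCOM and ≲0.3% for inertia against 1%/2%
  acceptance bands. Routine tests use 32–128 divisions.
- The Monte-Carlo oracle (ray-crossing parity, 10⁷ points for the 0.5%
  check) is implemented independently of the integrator and shares no
  code path with it.
- Cut conservation: child volumes from any single plane cut match the
  parent within 0.1% (observed ≈ machine precision for planar caps); the
  16-segment partition conserves volume within 0.5%.
- Degenerate inputs: open meshes are rejected with the boundary-edge
  count; zero-volume cuts raise "empty segment" with the label; faces
  lying exactly in a cut plane are assigned by outward-normal direction;
  a perfectly symmetric foot breaks its axis tie toward global ap with a
  warning.

## Known limitations

No mesh repair beyond the winding fix (holes and self-intersections must
be resolved upstream); no automatic landmark detection; non-planar
segment boundaries are not expressible; ECM accuracy depends on the
user-chosen slice thickness; the female regression model is proportional
rather than population-fitted and should not be used where sex-specific
accuracy matters; statistics assume complete repeated-measures matrices.
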