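# Methods

## Model and assumptions

`ssealign` assumes that the identity of a protein fold is captured by the
types, sequence order and pairwise geometry (interaxial angle, midpoint
distance) of its secondary-structure elements. Matching is
*topology-dependent*: aligned SSEs must respect sequence order in both
chains, so circular permutations and strand-order rearrangements are out
of reach by design. The method aligns single chains only, and produces
SSE-level (not residue-level) correspondences.

### SSE vectorization

- Per-residue labels come from DSSP output (classic or mmCIF dialect),
  an external `mkdssp` run, or a user string. Helix subtypes (DSSP H, G,
  I) merge into one helix class *before* length filtering, so a
  3₁₀-capped α-helix counts as one element.
- Minimum lengths are read strictly: helices survive with ≥ 5 residues,
  strands with ≥ 4. Gaps in residue numbering do not split a run; only
  label changes do.
- The axis is the first principal direction (SVD) of the element's
  mean-centered Cα coordinates, oriented N→C (flipped when opposing
  `last − first`); endpoints are the projections of the first and last
  residue, and the midpoint is the segment midpoint. Coincident points
  raise a degenerate-axis error.
- The interaxial angle ω is implemented as the torsion angle of
  (axis-1 direction, midpoint connection, axis-2 direction), signed, in
  (−180°, 180°]. The overall sign convention is immaterial downstream:
  only Δω with a 360° wraparound enters the scores, which makes results
  invariant to the handedness choice. When the midpoints coincide or an
  axis is parallel to the connection line the torsion is undefined and
  the unsigned angle between directions is substituted.

## Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| C | 45 | deg | score cap and mismatch penalty of the pair score |
| D | 20 | Å | contact cutoff on midpoint distances |
| g₁ | −4 | score | stage-1 gap opening (per contiguous gap) |
| g₂ | −4 | score | stage-2 gap opening |
| σ | 45 | deg | Gaussian scale of the raw score S |
| ΔD | = D | Å | delta-matrix reporting cutoff on Δd |
| mode ratio | 2 | — | semi-global switch: max(M,N)/min(M,N) > 2 (strict) |
| block angle | 90 | deg | subdiagonal ceiling of the block walk |
| block size | 3 | pairs | minimum rigid-block extent |

C, D and g₁ = g₂ = −4 are the calibrated working point of the method; C
bounds the pair score to {0} ∪ [−C, C] because Δω > 2C is clamped to −C.
σ has no independently calibrated value; it is set equal to C so that
the Gaussian tolerates angular noise on the same scale the DP does, and
is exposed as `--sigma`. ΔD defaults to D so the reporting filter never
suppresses a contact-consistent entry unless the user tightens it.
Contact is non-strict (d ≤ D); the boundary case is untestable in real
data and the choice is documented rather than load-bearing. Angles and
distances are stored for *all* pairs and the cutoff applied at scoring
time, so a precomputed database can be searched with any D.

## Dynamic programming

Both stages use a **constant gap-opening penalty model**: a contiguous
gap costs its opening penalty once and extensions are free (affine with
zero extension, implemented as Gotoh three-state recurrences). Stage 1
runs global alignment by default and semi-global — free leading and
trailing gaps on *both* rows — when the SSE counts are more than
two-fold apart; the optimum is the bottom-right cell (global) or the
maximum over the last row and column (semi-global). Stage 2 is standard
Smith–Waterman with a zero floor over the matrix of stage-1 optima.

Determinism: stage-2 backtracking starts at the maximum cell (ties:
smallest (i, k) lexicographically) and prefers diagonal, then up, then
left. Columns pairing SSEs of different types are *permitted* but carry
−C stage-1 contributions, so they never appear in positively scoring
regions; no extra hard filter is applied. An all-nonpositive stage-2
matrix yields an empty alignment, reported as S_r = 0.

## Scores

The raw score is S = Σᵢ exp(−Δωᵢ²/σ²) over the N reported delta-matrix
entries — those whose source pairs are contacts in both matrices and
whose Δd ≤ ΔD — so S = N for identical structures and S → 0 with
growing angular deviation. An alternative normalization that divides
the plain Gaussian sum by σ² is available
(`raw_score(..., form="scaled_sum")`) for auditability; it does not
satisfy the S = N identity and is not used anywhere. n_q and n_t count
*unordered* contact pairs of the full matrices, which makes
S_r = 100·2S/(n_q+n_t) and C_r = 100·S/min(n_q, n_t) exactly 100 on
self-comparison. QS = 2M/(|A|+|B|) compares SSE-pair sets; two empty
alignments define QS = 0 with a warning.

## Rigid blocks and superposition

The block walk inspects the first subdiagonal of the delta sub-matrix
(cell (k, k−1) couples aligned pairs k−1 and k). A reported value ≤ 90°
starts or extends a block; a suppressed (null) value trims it; a value
> 90° is rescued — the block continues — if the adjacent left-row cell
(k, k−2) or bottom-column cell (k+1, k−1) is reported and ≤ 90°,
otherwise it trims. Blocks smaller than three pairs are discarded. The
90° ceiling is a fixed constant of the block algorithm, independent of
C. "Null" means suppressed by the D/ΔD validity mask. Blocks are
maximal, disjoint, contiguous runs; non-adjacent runs are never merged.

Each block is superposed on the axis endpoints (start and end, two
points per member SSE) with the Kearsley quaternion solution: the
eigenvector of the smallest eigenvalue of the 4×4 matrix built from
coordinate sums and differences is the optimal rotation quaternion, and
the rotation is proper by construction. The RMSD is recomputed from the
explicit residuals rather than from the eigenvalue, which is numerically
cleaner near a perfect match (√λ amplifies eigensolver noise to ~1e-7).
Residue-level coordinates are transformed for output only — one model
per block in the written PDB.

## Synthetic constructs: what they do and do not show

The generator emits idealized Cα traces — helices with 1.5 Å rise,
100°/residue twist, 2.3 Å radius; strands with 3.4 Å rise and a 0.5 Å
alternating pleat — joined by straight coil linkers, with matching
label strings, optional isotropic Gaussian coordinate noise behind one
seeded RNG, and PDB export so the file-reading path is exercised. The
lateral drift that an incomplete helical turn induces in a line fit
(up to ~19° for short elements) is regressed out of each element, so
the fitted axis equals the requested direction by construction, at the
price of a tiny shear of the ideal geometry.

Hinge constructs model the moved domain as a rotation about a pivot
*offset beyond the domain* — a rigid-body shift. This choice is
deliberate: the block algorithm separates blocks only where the
junction delta entry is suppressed (distances changed beyond the
contact/reporting cutoffs) or exceeds 90°, so a pure small-angle
rotation about the inter-domain axis would legitimately remain one
block. The offset pivot makes 30°, 60° and 120° hinges all displace the
second domain out of cross-domain contact, giving an unambiguous
two-block ground truth. Consequently the moved partner chains are
*disconnected* constructs: self-comparing one correctly yields one
block per segment, which is why the identity checks run on the catalog
of connected fixtures (bundle, sheet, mixed fold, and the unmoved hinge
and three-segment chains).

Passing these suites shows the algorithmic contracts hold exactly; it
does not show robustness to real-data phenomena the generator omits:
bent or split SSEs, DSSP boundary uncertainty, missing residues inside
elements, sterics, or realistic loop geometry.

## Problem sizes and tolerances

The oracle suites use structures of 2–5 SSEs (200 random instances per
DP stage, exhaustive enumeration as the reference) and 100 random point
sets for the superposition cross-check (agreement to 1e-9; determinant
error ≤ 1e-9); fold-level checks use constructs of 4–9 SSEs. These
sizes make enumeration exact and keep the whole suite around a second.
Geometric identities are asserted at 1e-6–1e-9; statistical checks
(noise RMSD vs the σ²(3n−6)/n expectation) use a fixed seed and a
three-standard-error band.

## Known limitations

- Topology-dependent and single-chain; no non-sequential matching, no
  multi-chain or quaternary comparison.
- No internal secondary-structure assignment: DSSP output or a user
  string is required.
- SSE-level only: no residue-level alignment or residue RMSD
  optimization.
- No statistical significance model (p-values/E-values) for scores.
- Accuracy inherits the quality of the secondary-structure assignment;
  split or bent elements fragment the SSE sequence and can break
  otherwise contiguous matches.
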