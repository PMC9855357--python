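# Methods

This note records the models, conventions and numerical choices behind
`idrctd`, and what the synthetic-data generators do and do not emulate.

## Sequence charge patterning

Charges: R and K count +1, D and E count −1; histidine is treated as
neutral (pKa ≈ 6 leaves it essentially uncharged at pH 7.4) and the
termini contribute no charge because every analysed region is an internal
fragment of a membrane protein. FCR = f₊ + f₋ and NCPR = f₊ − f₋ are exact
counts divided by region length.

**Kappa.** Per blob window of g = 5 and g = 6 residues (stride 1) the
charge asymmetry σ = (f₊ − f₋)²/(f₊ + f₋) is computed (0 for uncharged
windows); δ_g is the mean squared deviation of the window σ from the
whole-sequence σ, and κ averages δ_g/δ_g^max over the two window sizes.
δ_g^max is the maximum of δ_g over a deterministic family of maximally
segregated arrangements of the same composition: (i) the two charge
species as contiguous blocks with neutrals distributed around and between
them, and (ii) "wrapped" layouts with one species split between the two
chain ends and the other centred. Family (ii) is required: for some
compositions (e.g. 2+/3−/3 neutral) the exhaustive-permutation optimum
splits a species, and a two-block-only search understates δ_max by a few
percent. The test-suite verifies equality with exhaustive enumeration to
1e−9 across all compositions up to length 10 and a sample beyond. κ is
undefined (NaN) for regions with fewer than two charged residues.

**Diagram of states.** Classification uses (f₊, f₋) only: weak
polyampholyte below FCR 0.25; intermediate for 0.25 ≤ FCR ≤ 0.35;
strong polyampholyte for FCR > 0.35 with both species ≤ 0.35;
positive/negative polyelectrolyte when a single species exceeds 0.35.
Boundaries are closed on the side written above (FCR = 0.25 is
intermediate, f₊ = 0.35 is not yet a polyelectrolyte), which makes the
partition total and deterministic.

**Hydropathy.** Kyte–Doolittle values are shifted from [−4.5, +4.5] onto
[0, 9] (so poly-Ile scores 9, poly-Arg 0), averaged in 5-residue sliding
windows, then averaged over windows. The 0–9 scale was chosen because the
published per-region values (3.3–3.8) are only consistent with this
magnitude, not with a 0–1 rescaling.

**Unpaired arginines.** A composition-level heuristic: acidic residues
(D+E) first neutralise lysines; any acidic excess then pairs arginines;
the remainder is "unpaired". It reproduces the intended arithmetic
qualitatively (fewer unpaired arginines where acidics are dense and
lysines scarce) and is exposed as a replaceable convention rather than a
physical model.

**Pairwise identity.** Needleman–Wunsch global alignment with BLOSUM62,
gap open 10 and extension 0.5; identity counts identical pairs over all
alignment columns including gap columns, similarity additionally counts
substitutions with positive BLOSUM62 score. Published identity figures
for these proteins are treated as reference points, not exact targets,
since the original alignment parameters are unrecorded.

## Packaged surrogate regions

The two packaged FASTA files are *synthetic surrogates* for the rat
GluN2A/GluN2B CTD2 subdomains, generated by `idrctd.synthetic`: the
composition counts reproduce the published FCR/NCPR exactly at three
decimals (58 charged of 222 for CTD2A; 48 of 233 for CTD2B), arginine and
aromatic positions are laid out to match the published spacing statistics
(mean gaps 10/21 residues for CTD2A R/aromatics, 19/22 for CTD2B), the
S/N-rich filler is balanced to the published windowed hydropathy, and the
remaining charged/filler positions are annealed to the published κ
values. Tests that use these fixtures therefore verify that the
measurement pipeline recovers known sequence statistics; they say nothing
about the actual database sequences. CTD2A is numbered 1243–1464: the
published FCR/NCPR are only representable at a length of 222 residues,
which identifies the subdomain as running to the GluN2A C-terminus
(1464), as CTD2B runs to its C-terminus (1482).

## Ensemble observables

Ensembles are multi-model PDB files (biotite handles parsing/writing) with
optional replica-temperature labels per model, written as `REMARK 250`
records or supplied in a sidecar CSV. Temperature selection keeps frames
whose label falls in a closed window (default use: 300–310 K); no
replica-exchange demultiplexing is attempted, matching how such windows
are used upstream.

- **Rg**: per frame, √(Σwᵢ|rᵢ−r_cm|²/Σwᵢ); uniform weights by default,
  atomic masses optional (which of the two the reference analysis used is
  unstated, so both are supported). Histograms use 1 Å bins by default and
  report the modal bin centre.
- **Contacts**: residues i, j are in contact in a frame iff any heavy-atom
  (element ≠ H) pair is within 6.5 Å; pairs with |i−j| < 2 are excluded
  ("non-sequential"), both the cutoff and the separation being parameters.
  Each unordered pair is counted once per frame and symmetrised, so the
  matrix is exactly symmetric.
- **Hydrogen bonds**: donor N–H to acceptor carbonyl O with
  d(N,O) ≤ 3.5 Å and angle(N–H⋯O) > 120°. When the amide hydrogen is
  absent from the coordinates it is reconstructed at 1.01 Å from N on the
  in-plane outward bisector of the C(prev)–N–CA angle; the chain's first
  residue and prolines have no donor, and the bond to the covalently
  adjacent carbonyl (acceptor = donor − 1) is excluded.
- **Secondary structure**: Kabsch–Sander-style patterns on the H-bond
  list — n-turns (i+n → i, n = 3, 4, 5), helices from two consecutive
  n-turns, bridges (parallel and antiparallel) from the classic two-bond
  patterns, turns from isolated n-turns. The 8-class vocabulary collapses
  as {H, G, I} → helix, {E, B} → sheet, {T} → turn, else coil. Occupancy
  profiles are per-residue class frequencies over frames and sum to 1 by
  construction. The assignment is cross-checked in tests against mdtraj's
  independent DSSP implementation on an ideal helix.

## smFRET analysis

Traces are tidy CSVs (molecule, frame, I_D, I_A, direct-excitation I_A)
at 10 frames/s. The proximity ratio E = I_A/(I_A + I_D) is deliberately
raw: no gamma, crosstalk or background corrections anywhere, matching the
quantity the population histograms are built from. Frames with
non-positive total intensity are flagged and skipped.

**Change points.** Steps are found by binary segmentation with a
CUSUM-style statistic; a split is accepted when its step size exceeds 3×
the robust noise SD (1.4826·MAD of first differences /√2). Photobleaching
is the first downward step of I_D + I_A. On simulated noisy single-step
traces the bleach frame is recovered within ±2 frames in >95% of cases.
Histogram accumulation truncates each trace at the first bleach of
*either* dye: the donor's death steps the summed intensity down, while the
acceptor's death conserves the sum (the donor rises) but steps the
direct-excitation channel down. Without the acceptor-side truncation,
post-acceptor-bleach frames (E ≈ 0, conformationally meaningless) leak
into the population histogram and masquerade as a zero-FRET state.

**Single-pair selection** requires (a) direct-excitation acceptor signal
above threshold (default 50 counts) while the acceptor lives, (b) at most
one downward step in both the summed intensity and the direct-excitation
channel (single-step bleaching; aggregates step more than once), and
(c) a donor intensity rise at the acceptor's bleach when the acceptor dies
first. Molecules are classified **dynamic** when the proximity ratio has a
change point whose donor/acceptor steps are anticorrelated while total
intensity is conserved (within 0.5× the larger channel step plus noise);
correlated steps (focus drift) do not qualify. No dwell-time kinetics are
extracted: at 10 Hz the underlying dynamics are faster than the frame
time, so histograms are time-averaged state distributions.

**Mixture model.** Histograms (default 50 bins on [0, 1]) are fitted with
mixtures of [0, 1]-truncated Gaussians by maximising the binned
multinomial likelihood (L-BFGS-B on logit weights, means, log sigmas; one
quantile-based start, one hierarchical start splitting the widest
component of the (k−1)-fit, and seeded random restarts). Truncation
matters: proximity ratios are bounded, and fitting untruncated Gaussians
to a state centred at 0.2 with FWHM 0.33 would bias its mean upward by
≈0.02. The state count k = 1…4 is selected as the smallest k whose BIC
(−2lnL + (3k−1)lnN) lies within 2 units of the minimum — a deterministic
parsimony criterion standing in for "minimise the fitting statistics".
Widths are reported as FWHM = 2√(2ln2)·σ. On seeded 20,000-frame synthetic
histograms at the published two- and three-state configurations, the fit
selects the correct k and recovers means within ±0.02 and occupancies
within ±0.05 in every one of 20 replicates.

## Polymer-model distance inversion

The SAW-ν reduced end-to-end distribution P(x) ∝ x^{2+g}e^{−αx^δ} with
x = r/√⟨r²⟩, g = (γ−1)/ν, δ = 1/(1−ν) uses ν = 0.5876 and γ = 1.1615; α
and the normalisation follow in closed form from gamma-function moment
identities (⟨x²⟩ = 1). ν = 0.5, γ = 1 recovers the Gaussian chain exactly,
exposed as `GAUSSIAN_CHAIN`. Given a mean proximity ratio, the scale whose
distribution-averaged efficiency ∫P(r)[1+(r/R₀)⁶]⁻¹dr matches it is found
by Brent root-finding (the map is strictly monotone; bracket
10⁻³R₀…10³R₀); the efficiency integral uses a 600-node Gauss–Legendre
rule on [0, 25] in reduced units (the density is negligible beyond
x ≈ 10), self-consistent to better than 1e−6.

Two conventions for the reported ⟨R_DA⟩ are provided: the distribution
scale √⟨r²⟩ (default) and the first moment ⟨r⟩ ≈ 0.937·√⟨r²⟩. The rms
convention is the default because it reproduces the published distance
table for this system at R₀ = 5.1 nm (four of five printed values inside
their printed uncertainties, the fifth within 0.06 nm), whereas the first
moment is uniformly 4–6% low. The Förster radius default of 5.1 nm is the
literature value for the Alexa 555/647 pair; the value actually used for
the published table is unrecorded and the results scale linearly with R₀,
so it is exposed prominently everywhere. In the rigid (zero-width) limit
E = 0.5 inverts to exactly R₀.

## Synthetic-data generators

All generators are deterministic given a seed and exist to give every
pipeline stage inputs with known ground truth; they emulate statistical
structure, not physics.

- **Sequences**: exact multiset composition; optional κ target reached by
  swap-only Metropolis annealing (geometric cooling from T = 0.05, factor
  0.9999, cap 10⁵ iterations, tolerance 0.01), which preserves composition
  by construction; positions can be pinned to control spacing statistics
  independently of the annealed charge pattern. Unreachable targets raise
  after the cap with the best value found.
- **Chains**: freely jointed chains (fixed 3.8 Å bonds, uniform random
  directions; ⟨Rg²⟩ → Nb²/6); excluded-volume chains sampled by the pivot
  algorithm over hard-sphere beads (default core radius 1.5 Å — the 3.0 Å
  diameter is below the bond length so bonded neighbours are always
  feasible; touching 1.9 Å beads would additionally forbid bond angles
  below 60° and stiffen short chains, inflating the finite-N scaling
  exponent), with 10N accepted pivots of burn-in from the rod start and
  N/2 accepted pivots between saved frames. The fitted Rg-vs-N exponent
  over N = 25–200 lands near 0.62 — above the asymptotic 0.588, as
  expected for short chains with strong excluded volume. Ideal-helix
  (φ = −57°, ψ = −47°; ≈100° twist and 1.5 Å rise per residue) and
  antiparallel paired-strand fixtures are built from standard backbone
  internal coordinates by NeRF chain extension, with amide H placed by
  the same bisector rule the H-bond detector uses; the second strand's
  rigid offset is grid-searched deterministically to maximise inter-strand
  H-bonds.
- **FRET traces**: states follow an exact continuous-time Markov jump
  chain; per-frame E is the dwell-time-weighted state mean plus the
  state's Gaussian width; each dye bleaches once with exponential waiting
  time; intensities get Gaussian noise with variance proportional to the
  noiseless signal (camera-like; a deliberate simplification of Poisson
  shot noise) plus a background floor; the direct-excitation channel
  follows acceptor aliveness. Multi-dye molecules superpose independent
  copies to exercise aggregate rejection. Not modelled: blinking,
  spectral crosstalk, gamma factors, diffusion — so passing tests
  demonstrate correct *algorithmic* behaviour, not robustness to every
  experimental artefact.

## Known limitations

- The surrogate sequences constrain what the sequence-level reference
  checks can claim (see above); on real database sequences the same code
  paths apply unchanged via `read_fasta_region`.
- κ's δ_max search is deterministic and verified exhaustively only on
  short sequences; a pathological composition could in principle exceed
  the searched families, which would make reported κ values slight
  overestimates of segregation (never above 1 for the arrangements
  searched).
- The secondary-structure assignment implements the backbone H-bond
  patterns only (no geometric kinks/bends), which is sufficient for the
  4-class collapse used here.
- The mixture fit treats bins as independent multinomial counts; for very
  sparse histograms (<3 occupied bins) it refuses to fit.
- Inverted distances inherit the R₀ assumption linearly; widths of the
  FRET states are *not* propagated into distance uncertainties.
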