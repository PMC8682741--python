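# Methods

prfkit models the computational pipeline of a deep mutational scan of −1
programmed ribosomal frameshifting (−1PRF) in an alphavirus structural
polyprotein, together with a coarse-grained simulator of the
translocon-mediated cotranslational folding that generates the pulling
forces coupled to frameshifting. This note records the models, their
assumptions, the parameters that matter, and the places where the design
was genuinely open.

## Coordinates and sequence model

All coordinates are 1-based inclusive: polyprotein residue numbers (the
mutagenized window runs I696–P817) and transcript base numbers (the
stem‑loop region near bases 2390–2419). A `PolyproteinRecord` pins both
numbering systems to a concrete fragment; the invariant is that residue
*r* occupies bases `first_nt + 3(r − first_res) … +2`. RNA is the internal
alphabet; FASTA I/O maps T↔U at the boundary.

No full viral genome ships with the package. A seeded fixture generator
embeds the experimentally printed pieces — the TM2 23‑mer
`LTPYALAPNAVIPTSLALLCCVR` at residues 725–747 and the slippery
heptanucleotide `U UUU UUA` — into random sense-codon flanks at
configurable coordinates (the slip-site P-site codon defaults to residue
789, which is configuration, not a constant of the biology). The stem‑1
base-pair list is consumed as an input table; RNA structure is never
predicted.

## Variant universes

The library model is NNN (not NNK) randomization of every 0‑frame codon
in a residue window with the wild-type codon excluded: 63 variants per
position, hence 122 × 63 = 7686 possible variants for 696–817. Slip-site
mutants are the exhaustive single/double/triple base substitutions of the
heptamer (21 + 189 + 945 = 1155); mutational load is classified per codon
(P site = heptamer bases 2–4, A site = bases 5–7, base 1 and the upstream
codon count as E-site hits). Amino-acid missense sets are 19 × length
(437 for TM2). Variant identifiers (`L725:CUU>AAA`) are canonical and
round-trip.

## Synthetic sort-seq generator

The generator emulates the experiment end to end, so the estimator can be
tested against a known truth:

* **Truth.** Each variant gets a true mean mKate:eGFP ratio μ_v (WT ≡ 1)
  from a three-class mixture: a null class log-normal around 1
  (σ = 0.1), a "down" class uniform on [0.35, 0.8] (bounded below by the
  assay floor), and an "up" class uniform on (1, 2.5]. Default weights
  0.7/0.2/0.1 give the observed shape of a mostly WT-like library with
  low and high tails.
* **Cells.** Each cell expresses one variant and draws a ratio
  `exp(Normal(ln μ_v, σ_cell))`; σ_cell defaults to 0.25 natural-log
  units (the single-cell spread of the reporter is not published; this is
  a free synthetic parameter). Variant abundances are uniform by default;
  a WT abundance of ~2% emulates the unmutagenized background carried by
  a recombined landing-pad library and guarantees the WT coverage that
  normalization requires.
* **Sorting.** Quartile gates are applied to the pooled population by
  rank (stable sort by ratio, ties resolved by cell index), so the four
  fractions are exactly 25% up to the division remainder even for
  degenerate (zero-noise) populations. Per-bin mean intensities I_b and
  fractions F_b are computed from the realized cells.
* **Sequencing.** Reads per bin are multinomial in the bin's cellular
  composition at a configurable depth (desk default 2×10⁴ reads/bin;
  the experiment's 2×10⁶ is reachable by argument), with an optional
  symmetric mis-assignment rate ε (default 0 — quality-filtered counts
  are modeled, not raw sequencer output). An optional FASTQ path emits
  error-free paired reads (Q40) whose exact-match calling reproduces the
  count table bit for bit.

What the generator does **not** model: PCR bias, per-base sequencing
error, recombination efficiency, growth between sort and harvest. Passing
tests therefore demonstrate correctness of the inference given the
sampling model, not robustness to those real-data artifacts.

## Score inference

The estimator is the standard count-based sort-seq score: a variant's
read fraction per bin is rescaled to a cell fraction by F_b, and the raw
score is the weighted mean of bin mean intensities,
`w_vb = (c_vb/Σ_v c_vb)·F_b`, `raw_v = Σ w I / Σ w`, normalized to WT.
Because raw scores are convex combinations of I_1…I_4, the smallest
assignable relative score is I_1/raw(WT) — the structural "floor" of the
assay (0.35 in the experiment). Variants under `min_reads` (default 20)
are flagged out rather than dropped; a missing or under-covered WT is
fatal. Replicates merge by unweighted mean over passing replicates, with
pairwise Pearson r reported as QC.

At desk scale (10⁴ variants, 10⁵ cells, 2×10⁴ reads/bin ≈ 8
reads/variant) recovery of the truth is limited by read sampling and by
quartile saturation; correlation with truth is ≈0.81 over all variants,
≈0.9 over read-filter-passing variants, and ≈0.93 at the experiment's
depth where only saturation remains. Synthetic replicate agreement at
this scale (r ≈ 0.8) happens to sit in the experimentally reported band.

## Codon decoding score

A sense codon's score is the summed relative abundance of every tRNA that
can decode it. Pairing is strict Watson–Crick at codon positions 1–2
(anticodon 36/35) and rule-based at codon position 3 / anticodon 34. The
default wobble table is the classic set with A34 read as inosine
(I pairs U/C/A; G34 pairs C/U; U34 pairs A/G; C34 pairs G); it is fully
configurable because the operational rule set behind the published score
is not printed. Stop codons raise an error rather than scoring zero —
no tRNA occupies the A site productively. Abundance tables are TSV inputs
with replicate columns averaged on load; a seeded synthetic table ships
for download-free tests.

## Effect maps

Figure-level aggregations are deliberately plain: per-position means over
the ≤3 single-nucleotide substitutions, sample SD (n−1) over the ≤19
missense substitutions per residue, and box statistics
(10/25/50/75/90th percentiles, linear interpolation between order
statistics — the convention is pinned because box-plot percentiles vary
across software) per slip-site mutational load. Matrices mask wild-type
cells and propagate missingness as NA (never 0). Amino-acid rows order by
descending hydrophobicity under a configurable scale — default the
biological (translocon insertion) scale, Kyte–Doolittle available — with
alphabetical tie-breaks; codon rows order by descending decoding score.
The published figure does not name its ordering scale; the choice only
permutes rows.

## Coarse-grained translocon simulator

### Representation

The nascent chain is a bead-spring polymer, one bead per three residues;
a short final bead keeps its actual residues. Each bead carries the sum
of its residues' water→bilayer transfer free energies (biological
hydrophobicity scale) and formal charges (K/R = +1, D/E = −1). Overdamped
Langevin dynamics with dt = 300 ns and D = 253 nm²/s evolves the beads:
`x ← x + (D/kT)F dt + √(2D dt)η`, kT = 0.593 kcal/mol. Beads appear at
the PTC tether anchor at the translation rate (default 5 aa/s; one bead
per 3/rate seconds).

### Geometry (idealized-parametric)

Cryo-EM meshes are not used; every behavior tested depends only on the
topology of the compartments. With +z cytosolic and −z lumenal: an
exit-tunnel stub (radius 0.9 nm) above a sealed ribosome–translocon
junction (radius 1.2 nm), a channel of radius 1.2 nm through a membrane
slab |z| ≤ 2 nm, a lateral-gate corridor opening toward +x into a bilayer
patch of finite lateral extent (x ≤ 3 nm), and a shallow lumen below.
Hard walls are enforced by rejection: a proposed displacement landing in
a forbidden region is re-drawn with fresh noise; a bead whose current
position became forbidden (gate closed behind it) moves freely. The exit
tunnel is truncated: 27 unmodeled residues are added to the index of the
final bead when deciding arrest, so the chain arrests when
`3·n_beads + 27 ≥ slip_res − start_res + 1`. Translation starts 33
residues upstream of TM1 (696 − 33 = 663 for the study construct).

Two geometric choices deserve emphasis because they were calibrated
during model development (against the package's own polarity controls,
not against any published number — the source model's parameterization
lives in prior work and is not printed):

* **Finite bilayer patch.** An unbounded implicit bilayer lets an
  integrated TM helix diffuse arbitrarily far from the translocon, which
  makes the tether tension an accident of how far it wandered. Capping
  the corridor at 3 nm represents the local lipid environment at the
  gate and keeps the integrated state geometrically defined.
* **Shallow lumen (1 nm).** A deep empty lumen acts as an entropic
  ratchet that pulls any translocating chain and swamps the
  integration-specific force with a sequence-independent baseline. Real
  lumens are crowded; truncating the compartment suppresses the
  artifact.

### Energetics

* **Membrane coupling.** Each bead's effective transfer energy is
  `h = lipid_scale·g + charge_penalty·|q|` with `lipid_scale = 2.5`
  (coarse-grained scales routinely require amplification to reproduce
  partitioning at the bead level) and 1.5 kcal/mol per unit charge. The
  bilayer exposure field is a smooth product of a z-profile over the slab
  and a lateral sigmoid centered just outside the channel wall.
  Hydrophobic beads additionally keep a residual fraction (0.35) of the
  slab coupling inside the channel — the gate-facing pore surface — which
  guides TM segments into the slab region; polar beads see a purely
  aqueous pore, so translocation of loops is unimpeded. This asymmetry
  matters: a symmetric residual coupling stalls polar translocation
  entirely.
* **Chain.** Harmonic bonds (k = 10 kcal/mol/nm², r₀ = 0.8 nm), soft
  quadratic excluded volume between non-bonded beads (10 kcal/mol,
  σ = 0.6 nm), and bending stiffness `k_ang(1 − cos θ)` that is small for
  polar beads (0.3 kcal/mol) and large for hydrophobic beads
  (4 kcal/mol): hydrophobic stretches behave as helical rods. The rod
  stiffness is what makes a membrane-spanning pose an attractor — a fully
  flexible hydrophobic string prefers interfacial blobs.
* **Tether.** The newest bead is held at the PTC anchor by a spring of
  10 kcal/mol/nm². The measured pulling force is the tether tension
  projected on the tunnel axis, in pN (1 kcal/mol/nm = 6.9477 pN). The
  spring is deliberately soft: thermal tension noise scales as √(kT·k),
  and a stiff tether buries few-pN signals under ~40 pN of thermal noise
  at desk-scale sampling. A config switch (`force_mode="nbead"`) instead
  reports the net axial force on the most N-terminal bead; the published
  phrase "forces exerted on the N-terminal bead" is ambiguous between the
  two and neither is asserted as its intent.
* **Lateral gate.** Two-state Metropolis switching every 1 ms with
  open−closed free energy `2.0 + 0.75·Σg` over beads in the gate region
  (channel interior plus a 0.6 nm shell, within the slab); a hydrophobic
  occupant favors opening. Detailed balance holds at fixed occupancy.

### Protocols

* **Force protocol.** Grow to the arrest bead count, hold for the
  window (3 s at full scale), sample tension every 3 ms. Sampling
  convention: samples at the start of each interval, `ceil(window/3 ms)`
  of them (3 s → 1000, 0.8 s → 267). Trajectories whose TM1 has not
  reached the N_out topology (N-flank bead below the lumenal face,
  evaluated at the end of the hold) are excluded; optionally TM1 can be
  restrained into its membrane-spanning N_out pose instead (the same
  device the topology protocol uses), which is how the reduced-scale
  mechanism tests isolate the TM2 contribution — the paper-style
  filter-and-drop approach needs trajectory counts a desk run cannot
  afford.
* **Topology protocol.** Translate the full construct without pausing
  (TM1 restrained: central bead held at the gate exit with a
  force-capped harmonic, N-flank pushed below the lumenal face), release
  the chain from the PTC (the ribosome stays docked, so the compartments
  are unchanged), relax, and classify TM2: *integrated* when its central
  beads lie inside the slab **and laterally in the bilayer patch** with
  the flanking beads on opposite membrane faces; *translocated* when the
  segment's mean position is below the slab; otherwise
  *cytosolic/other*. The lateral-lipid clause is an addition to the
  plain "in slab + flanks opposite" rule: without it a chain merely
  threading the channel counts as integrated, and in this geometry a
  polar chain can remain threaded indefinitely. Integration probability
  is reported with a Wilson 95% CI.
* **Rate sweep.** The force protocol at several translation rates,
  averaging over 0.8 s (full scale) per the study design.

### Desk-scale operation

Protocol durations shrink through `growth_time_scale` (the factor on the
interval between bead additions; 0.01 in the shipped tests, so biogenesis
takes hundreds of ms instead of tens of seconds), 0.3 s hold/relax
windows, and 20–30 trajectories; dt, D and all energetics are unchanged,
and full-scale values (factor 1, 3 s windows, 100 trajectories) are
plain configuration. Consequences worth knowing:

* The poly-Leu vs poly-Asn TM2 force separation is robust
  (≈8–9 vs ≈4 pN, far beyond 2 SEM at 20 trajectories). The arrest
  register of the bundled test construct leaves three linker beads
  between TM2 and the tether — short enough to stay taut while TM2 is
  membrane-inserted, which is what transmits the integration force.
* TM2 integration probability for poly-Leu plateaus at ≈0.5–0.7 within a
  0.3–0.45 s relax window (bilayer partitioning of the spanning helix
  out of the channel has a ≈0.3 s timescale in this model); poly-Asn is
  ≈0. The polarity ladder is monotone but switch-like: 3-residue
  coarse-graining means mixed rungs contain few genuinely hydrophobic
  beads.
* The translation-rate dependence of the mean force is flat within noise
  at compressed growth: the rate effect requires integration kinetics
  slower than the averaging window, which time compression removes. The
  slow-rate force is never significantly below the fast-rate force,
  which is the property asserted.

### Degenerate inputs and numerical guards

Bond stretch is monitored every segment and an integration is aborted if
any bond exceeds 2.5 nm (never observed under defaults). Restraint forces
are capped at `k × 1 nm` so a freshly emitted bead is steered, not
slammed through the chain. Harmonic/soft potentials keep per-step drift
two orders of magnitude below the thermal step, so the rejection scheme's
wall bias is negligible; the free-bead diffusion law 6Dt is reproduced to
within a few percent.

## Reproducibility

Every stochastic component consumes a `numpy` Generator seeded from an
explicit integer; the CGMD engine draws one 31-bit seed per kernel
segment from its trajectory generator, so any protocol is bit-identical
under a fixed seed on a single thread. The CLI derives per-stage child
seeds from the global seed by hashing, so stages are independently
reproducible.

## Known limitations

No PCR/sequencing error model beyond symmetric misassignment; no
Bayesian or ML scoring; no RNA structure prediction; no atomistic
simulation, explicit lipids, ribosome conformational dynamics, or a
transfer function from pulling force to −1PRF efficiency (the study
reports a correlation, not a mapping). The CG geometry is idealized;
absolute force values in pN are model-scale quantities and only
comparisons between sequences or conditions are meaningful.
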