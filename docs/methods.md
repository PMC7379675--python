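# Methods

This note documents the models behind `dsbkit`: what each stage assumes,
which parameters matter, what the synthetic inputs do and do not emulate,
and the numerical conventions. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Damage model

A deposition event is attributed to its **nearest atom in the whole
structure** (scipy KD-tree over every DNA, base and obstacle atom). The
event's energy accrues to a nucleotide's backbone tally iff that nearest
atom (a) belongs to the sugar-phosphate group
{P, OP1, OP2, O5', C5', C4', O4', C3', O3', C2', C1'} and (b) lies within
the **capture radius** (default 0.35 nm, covalent-bond scale — a tunable
of this model, not a measured quantity). Deposits nearest to base,
protein, or ion atoms count toward dose only. Nearest-atom-overall with a
radius gate prevents one deposit scoring on two nucleotides and keeps
base/histone hits from breaking the backbone. Distance ties resolve to the
atom earliest in (chain id, residue number, atom name) order, so scoring
is deterministic.

Energy is **accumulated per nucleotide across all events** of an exposure
before thresholding; an SSB is a tally ≥ ET, with the comparison
*inclusive* (≥ ET, and ≤ BPT for pairing — "within 10 bp" reads as
inclusive). A per-deposit variant (`DamageParams(per_deposit=True)`,
thresholding the largest single deposit instead of the sum) is provided
for sensitivity analysis.

DSBs are disjoint opposite-strand SSB pairs with |Δbp| ≤ BPT, counted by a
greedy sweep (ascending strand-1 breaks, each matched to the lowest
unused strand-2 break in its window). For uniform windows the greedy count
equals the maximum bipartite matching; the test suite verifies this
against Hopcroft–Karp on 10⁴ random break sets. The per-molecule endpoint
is binary (`broken` ⇔ dsb_count ≥ 1): a molecule with five DSBs counts
once, mirroring dosimeters that detect severance, not multiplicity.

Defaults: ET = 19 eV, BPT = 10 bp — the centre of the agreement region
reported for this class of model; scans default to ET ∈
{10, 12.5, 15, 17.5, 18, 19, 20, 22.5} eV and BPT ∈ {6, 8, 10, 12, 14} bp.

## Geometry

`parse_pdb` (gemmi) accepts any PDB with DA/DC/DG/DT (or legacy A/C/G/T)
residues. Nucleic chains alternate strand 1 / strand 2 in file order;
non-nucleic residues (histones, ions) are retained as non-scorable
absorbers by default (`histones_absorb=False` drops them). Å are converted
to nm on read; nm is the internal unit throughout.

`pair_strands` assigns `bp_index` geometrically: strand-1 nucleotides are
numbered in sequence order, and each strand-2 nucleotide claims its
nearest strand-1 partner by C1'–C1' distance under a 1.2 nm cutoff
(closest claim first, ties to the lowest residue number); leftover
nucleotides are flagged unpaired. The base-pair separation of two breaks
is |bp_index₁ − bp_index₂| with 0-based indices.

`build_bdna_fixture` generates an ideal duplex with the canonical B-DNA
rise (0.34 nm) and twist (36°) and coarse pseudo-atoms per nucleotide
(P, O5', C5', C4', C3', O3', C1' + one base site). One deliberate
simplification: the C1' pairing anchor sits at a reduced helical radius
(0.25 nm, diametrically across the axis) rather than the crystallographic
~0.59 nm. With realistic radii and a 36° twist, the geometrically nearest
cross-strand C1' is the i−1 neighbour, not the Watson–Crick partner, so
nearest-neighbour pairing would misregister on a coarse model that lacks
the base-plane geometry real pairing relies on. The reduced radius makes
the partner unambiguously nearest (0.50 nm vs 0.58 nm) while leaving the
backbone ring, rise and twist at B-DNA values. Fixtures therefore
exercise the pairing, assignment and scoring machinery faithfully but are
not stereochemically accurate B-DNA.

The **dose denominator** is the bounding-box volume at liquid-water
density ("box-water"; 12 × 15 × 25 nm ↔ 4.5 × 10⁻²¹ kg). An "atomic"
mode (sum of atomic masses) exists for sensitivity analysis. Gy is
J/kg in this scoring mass.

## Track model

Transport is a **declared parametric stand-in**, not track-structure
physics:

- each primary's energy is drawn from the spectrum;
- it crosses the scoring box on a straight **μ-random chord**: entry
  uniform on a bounding sphere (half-diagonal × 1.01), direction
  cosine-weighted about the inward normal — the isotropic-fluence
  convention, under which chords of the box are μ-random and the mean
  chord length is exactly 4V/S (verified by simulation against that
  closed form);
- interaction sites follow a Poisson process along the chord with linear
  density LET(E)/⟨ε⟩, where LET comes from an editable log-log-interpolated
  stopping table (packaged defaults are illustrative water values) and
  ⟨ε⟩ = `mean_deposit_ev` (default 40 eV);
- each site deposits a truncated-exponential energy (underlying scale
  ⟨ε⟩, truncated to [5, 500] eV by inverse-CDF).

Straight chords, energy-independent deposits and the absence of secondary
electrons are the model's major idealizations. In particular it has **no
end-of-track clustering**: real sub-keV electrons stop inside the volume
and dump tens of eV within a few nm, which is precisely what makes DSBs at
clinical doses possible.

**Dose scale.** That omission has a quantitative consequence users must
know. With the box-water denominator, the expected deposited energy at
dose D is D·m/e: for a naked 20-bp fixture (m ≈ 2.4 × 10⁻²³ kg) even
200 Gy corresponds to ~0.03 eV — far below one 40 eV interaction — so the
parametric model yields P(DSB) ≈ 0 across 25–200 Gy, and the package
reports exactly that when asked. Simulator-driven demonstrations (scan
monotonicity, dose-response shape) are therefore run at molecule-scale
doses of 10⁵–10⁶ Gy, where the expected deposit multiplicity reaches the
few-per-molecule regime that a real track-structure chain attains at
25–200 Gy through end-of-track clustering. Absolute simulated P(DSB)
values are **not** comparable with measured dose–response tables; all
threshold *orderings* (P(DSB) non-increasing in ET, non-decreasing in
BPT, the 8.22 eV threshold saturating relative to 19 eV) are exact on
shared event streams and are asserted as such.

## Exposure protocol and statistics

Primary counts are calibrated linearly from a pilot exposure
(`calibrate_primaries`: round(D_target · N_pilot / D_pilot); a 3 × 10⁵
primary pilot at 25 Gy scales to exactly 2.4 × 10⁶ at 200 Gy). Drivers
clamp the count at ≥ 1 primary. Each (dose, replicate) cell gets its own
seed, `base_seed + 1 + dose_index · n_replicates + replicate`, so no two
exposures share a stream (the pilot uses `base_seed` itself); a single
base seed reproduces every output bit-for-bit. The default replicate
count is 1000, the protocol's value; tests and the acceptance script use
50–200 replicates to stay desk-scale, which widens SEM by √(1000/N) but
changes no expectation.

Threshold scans generate events once per (dose, replicate) and re-score
them for every (ET, BPT) cell. This is statistically identical to
independent streams for any per-cell estimate, makes the ET/BPT
monotonicity exact rather than statistical, and is flagged in the run
log.

`estimate_pdsb` uses the sample SD (N−1) of the 0/1 outcomes, so
SEM = √(p(1−p)·N/(N−1))/√N; it refuses N < 2. The quadratic dose–response
fit is unweighted least squares of p on (D², D, 1) — the packaged
experimental table (25–200 Gy) yields b = 1.666 × 10⁻³ Gy⁻¹ (1.7 × 10⁻³
at two significant figures), with a and c not matching a previously
printed quadratic for the same data at face value; fit weighting
conventions differ enough that only b is treated as reproducible, and the
tests assert all three coefficients only against an independent
normal-equations solve.

## Synthetic spectrum

`synth_linac_spectrum` is a stand-in for a phase-space-derived 6 MV LINAC
electron spectrum. It matches two constraints only: the 6 MeV endpoint
and the cumulative fraction of electrons below 1 MeV (default 52%, pinned
exactly by piecewise rescaling of an exponential-shaped density,
scale 0.5 MeV). Bin contents of any measured spectrum are *not*
reproduced — no numbers are read off figures. The sub-MeV fraction is
interpreted as a fraction of *electrons*; `frac_is_energy_weighted=True`
switches to fraction of carried energy, since the phrasing is ambiguous
in parts of the literature. `truncate_spectrum(spec, 1.0)` reproduces the
argument that >1 MeV electrons (range ≫ molecule) contribute negligibly.

## Degenerate inputs and numerical conventions

- Spectrum probabilities are renormalized when they sum within 10⁻¹² of
  1, rejected at ≤ 0 total; in-bin sampling is uniform on (lower, upper]
  so energies stay strictly positive.
- An exposure may deposit nothing; `calibrate_primaries` raises on a
  zero-dose pilot, and the drivers grow the pilot (×4, up to 10 times)
  until energy lands.
- PDB round-trips preserve positions to the 0.001 Å column precision;
  tests compare at 5 × 10⁻⁵ nm.
- Residues with no backbone atoms at all are skipped (they cannot carry a
  strand break); protein-only files raise "not a DNA structure".
- The KD-tree is cached per geometry object; mutating a geometry's atoms
  invalidates the cache via the atom-table length check only, so treat
  geometries as immutable after construction.

## Known limitations

- No chemistry stage: indirect (radical-mediated) damage is out of scope,
  as is any complex-damage taxonomy (DSB+, base damage) or repair.
- No mmCIF input; histones are inert absorbers, never damage targets.
- The stopping table and deposit-energy parameters are illustrative; the
  package makes no claim of agreement with condensed-history or
  track-structure codes, and absolute P(DSB) values at clinical doses are
  outside what this track model can produce (see "Dose scale").
- Strand assignment alternates nucleic chains in file order; exotic
  multi-duplex PDB entries may need manual chain curation.
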