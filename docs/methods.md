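# Methods

## The analysis model

The pipeline targets a three-condition isobaric-labeling design:
unstimulated **control**, **acute** stimulation (bolus ligand,
minutes), and **chronic** stimulation (sustained ligand expression,
days). Each analyte — a protein or a phosphopeptide isoform — is
observed as reporter-ion signal-to-noise (S/N) per labeled channel.

**Relative abundance.** Per analyte, each channel's S/N is divided by
the row sum and scaled to 100. This removes analyte-specific loading
and ionization efficiency; all downstream quantities are ratios of
these row-normalized values, so the scaling constant cancels. Rows
summing to zero carry no information and are dropped (counted in the
log and manifest).

**Localization gate.** Phosphosite assignments with localization score
(AScore) ≤ 13 are removed before any site-level analysis; the cut is
strictly `score > 13`, the conventional P < 0.05 confidence point. A
missing score routes the record to the discard pile with its own
reason code rather than silently passing.

**Protein normalization.** Phosphopeptide relative abundance is divided
channel-wise by the parent protein's relative abundance, so that a
change in protein expression does not read as a phosphorylation
change. Sites whose protein was not quantified are flagged
`unnormalized` and carried forward with raw values — dropping them
would silently bias against low-abundance proteins. A protein value of
exactly 0 in a channel makes that channel's normalized value missing.

**Contrasts.** Replicate channels are collapsed to the per-condition
arithmetic mean (missing channels excluded). Per site:
`log2FC_acute = log2(acute/control)`, `log2FC_chronic =
log2(chronic/control)`, and the chronic-vs-acute `differential`,
computed as the difference of the two vs-control contrasts so the
identity `differential = log2FC_chronic − log2FC_acute` holds exactly
in floating point. No pseudocounts: any nonpositive condition mean
propagates a missing contrast with a logged reason, because inventing
a fold change for a zero measurement is worse than reporting none.

**Multisite isoforms.** Quantitation attaches to the peptide isoform;
an isoform carrying several phosphosites (e.g. S235/S236) is exploded
into one record per site, each inheriting the isoform's quant linkage.
This mirrors MS reality — the isoform, not the site, is quantified —
and means sites of one isoform share values by construction.

## Database merge

MS sites are matched into a phosphorylation-site reference
(tab-separated, `GENE / PROTEIN / ACC_ID / ORGANISM / MOD_RSD /
SITE_+/-7_AA` columns, up to a 3-line preamble tolerated) with a
tiered, first-hit-wins policy:

1. (normalized accession, residue, position), same organism;
2. (case-folded gene symbol, residue, position), same organism;
3. exact 15-mer flanking-window string, any organism.

Accession normalization strips isoform (`-2`) and version (`.1`)
suffixes. Tier 2 absorbs accession drift between releases; tier 3 is
the only route to cross-species curation (human/rat records for mouse
data), a deliberately conservative use of it. The winning tier is
recorded per match, duplicate reference keys within a tier are counted
and the first occurrence used, and the matched/unmatched partition is
exhaustive by construction. The exact key/fallback rules of published
in-house merges are rarely stated; the tier set is configurable
(`MatchPolicy`) so alternatives can be compared. Kinase annotation
then keys the kinase–substrate dataset on the matched reference
(accession, residue, position).

## Group statistics

Sites are assigned one functional-group label from a table that may
mix protein-level and site-level rows; a site-level row wins over the
protein-level row for its protein, and unknown keys become
`unclassified`.

**KS scan.** Each group (and each kinase's substrate set) is tested
against its complement with the two-sample Kolmogorov–Smirnov
statistic, `D = sup |F̂_x − F̂_y|` evaluated at the pooled sorted unique
points with right-continuous ECDFs (ties therefore contribute one
evaluation point). The asymptotic p uses the Kolmogorov distribution
at `√(nm/(n+m))·D`; a permutation mode computes the add-one-smoothed
tail frequency over seeded relabelings and matches exhaustive
enumeration on small inputs. Group-vs-complement (rather than all
pairwise) is the default because the scan's purpose is a per-group
ranking of "most differentially regulated"; a pairwise mode exists
behind a flag. Groups below a minimum size (default 5; the scans in
the calibration studies use 20) are skipped and logged. P-values are
Benjamini–Hochberg adjusted within each scan — the procedure is named
in the output since "FDR" alone is ambiguous.

**Outliers and enrichment.** Outliers are sites whose chosen contrast
(default: the chronic-vs-acute differential) strictly exceeds ±1 log2
units. Their proteins are tested for term over-representation with
the upper-tail hypergeometric probability `P(X ≥ k)` against the
phosphoprotein background, BH-adjusted across terms; terms absent from
the background are skipped. The term table is a plain GMT file, so any
annotation source (including real GO exports) can be supplied; no
external service is queried and no ontology-graph propagation is
performed.

## Signaling-map audit

Maps are SBML Level 2 with the CellDesigner extension namespace.
Species and reactions come from the standard elements; phosphosites
from extension modification residues in state "phosphorylated",
resolved through the protein definitions (residue names like `S235`,
or a bare residue letter when the position is uncurated — positionless
sites are tallied separately and excluded from concordance
denominators). PMIDs are extracted from reaction notes by the pattern
`PMID[:\s]*(\d+)`; only reaction-level PMIDs count as publications.
Union summaries deduplicate species by (name, compartment) and
reactions by id. Concordance matches map sites to the reference by
case-folded protein/gene name plus residue and position, because
curated maps label proteins by name, not accession.

## Network export

One node per kinase and per annotated site (label `GENE_S123`;
kinase node ids are prefixed so an autophosphorylation site never
collapses into its kinase as a self-loop), one deduplicated edge per
(kinase, site) pair carrying both contrasts, so either can drive edge
coloring. Exports are canonically ordered (sorted nodes and edges) and
therefore byte-stable; missing fold changes are empty fields in TSV
and omitted keys in GraphML.

## Synthetic-data generator

The generator emulates the study design, not raw spectra. Protein S/N is log-normal
(`2^(7 + N(0, baseline_sd) + condition effect + channel noise)`);
phosphopeptide S/N is the parent protein's realized channel value
times a site multiplier `2^α` (acute) or `2^(α+δ)` (chronic) times
channel noise, with `α ~ N(0, 0.8)` so roughly half the sites go up
under acute stimulation, and `δ` the planted chronic-vs-acute group
shift. Because the phosphopeptide inherits the protein's realized
value, protein normalization cancels protein effects exactly up to
measurement noise — which is precisely what that stage is for.

Key defaults and why:

- `n_proteins = 7528`, `n_phosphoproteins = 1847`, sites-per-protein
  distribution over 1..10 with 73.6% of proteins at 1–3 sites and mean
  ≈ 3.1 — the study scale (~5,750 localized sites).
- `n_replicates_per_condition = 3`, collapsed by mean. The emulated
  study pooled biological triplicates before labeling and does not
  state the channel layout; the simulated design is an assumption,
  flagged in the run manifest.
- `noise_sd_log2 = 0.58` per channel. With triplicate collapse and
  protein normalization this gives the null chronic-vs-acute
  differential an sd of ≈ 0.47 log2 units, i.e. ≈ 96.5% of null sites
  inside ±1 — the observed dispersion of such experiments. Power and
  recovery studies use 0.3 with explicit planted shifts.
- `frac_sites_in_reference = 0.903`, with small fractions of
  reference rows recorded under a renamed accession (tier-2 food) or a
  human/rat accession (tier-3 food), plus 5,000 decoy reference sites.
- `frac_matched_with_kinase = 0.066` of in-reference sites, kinase
  labels drawn Zipf-weighted from 408 kinases: curated kinase usage is
  heavy-tailed, and a uniform draw would wildly overestimate the
  distinct-kinase count at a few hundred annotated sites.
- `frac_below_localization_threshold = 0.05`: low-confidence peptides
  are generated on top of the configured site counts, so the
  post-filter scale is the configured one.
- Site positions are placed without replacement in proteins of 100–
  2,000 aa whose length grows with site count; flanking windows are
  random 15-mers with the phosphoacceptor (lowercase) at the center.

All randomness flows from a single seed through per-operation
independent streams, so identical configs reproduce every output file
byte-identically, regardless of which subset of generators is called.

What the generator does **not** emulate: missing-value mechanisms of
MS acquisition, isotopic impurity/interference, peptide sequences
beyond the flanking window, correlated biological pathway structure
beyond the planted group shifts, and non-uniform site-to-protein
enrichment biases. Passing tests therefore demonstrate correctness of
the computation under the stated statistical model, not robustness to
every artifact of real MS data.

## Numerical and design choices

- Row-sum conservation is enforced to 1e-9 relative tolerance;
  contrasts are exact in floating point by construction.
- KS ties: pooled-unique-point evaluation removes ambiguity; the
  permutation p uses `(1 + #{D* ≥ D}) / (1 + n_perm)` with a 1e-12
  slack on the comparison to absorb float noise in recomputed D.
- BH q-values come from statsmodels' `multipletests(method="fdr_bh")`.
- Scan problem sizes in the test and acceptance studies (100 null
  simulations with eight 20-site groups; 50 power runs with 50-site
  groups at noise 0.3; study-scale single runs of ~5,750 sites) were
  chosen as the smallest sizes at which the binomial calibration bands
  and ≥90% detection targets are meaningful.
- The chronic-vs-acute differential is computed on protein-normalized
  values, the same stream as the vs-control contrasts; whether the
  original figure used normalized or raw values for its y-axis is not
  documented, so this is a declared choice (the raw stream can be
  obtained by passing an identity protein table).

## Known limitations

- Tier-3 matching requires flanking windows on the MS side; records
  without windows simply cannot cross species.
- Asymptotic KS p-values are approximate below ~20 observations per
  side; the permutation mode is the fallback for small groups.
- The hypergeometric test treats proteins as exchangeable; proteins
  with many phosphosites are more likely to contribute an outlier, a
  dependence the test ignores (visible as mild anti-conservatism when
  term membership correlates with site count).
- Map concordance is name-based; an alias table is needed when map
  labels differ from database gene symbols.
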