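# Methods

## Gold standard from enzymatic plausibility

Inhibitor families are mapped to the protease catalytic classes they can
block (`CompatibilityRule`). Every inhibitor × protease pair is then
partitioned: annotated inhibitions are TP; unannotated pairs whose protease
class is incompatible with the inhibitor family are TN; the rest — the
genuine search space — are unknown. An annotated pair that contradicts its
rule stays TP (curated data outranks the heuristic) but is recorded in a
conflict report with a warning. Catalytically dead homologs (`active=False`)
remain in the search space; interaction data does not distinguish them.

TP:TN enrichment tables are the accounting device for filters. Two ratio
formats are supported: percent (100·TP/TN, two decimals) and "1:n"
(TN per TP; one decimal below 10, integer at or above 10 — the precision
that published cascade tables use). `enrichment_table` requires every stage
to be contained in the first stage (the universe) but not necessarily in
its predecessor, because breakdown-style tables (colocalized /
antilocalized / missing) partition the universe rather than nest;
`run_cascade` additionally enforces strict nesting for its own stages,
which are genuinely sequential filters.

## Coexpression matrices

Correlations are computed on log10-transformed values with zeros floored at
0.01 (configurable; Spearman is unaffected by the monotone transform,
Pearson is stabilised against zero inflation). Zero-variance genes yield
missing scores rather than errors. Spearman is implemented as Pearson on
average ranks, so tie handling matches the conventional definition exactly.

The element-wise maximum of the Pearson and Spearman matrices takes the
signed maximum per pair (an absolute-value variant is available); where one
matrix is missing a score the other's is used. Per-tissue matrices require
at least 3 samples per tissue (smaller tissues are skipped with a warning)
and their average is the per-pair unweighted mean over matrices where the
pair is scored. Meta-analysis over several datasets either z-scores each
dataset per gene and concatenates columns before one correlation pass
("merged" — the z-scoring prevents between-dataset location/scale offsets
from manufacturing correlation), or averages per-dataset correlation
matrices ("averaged").

Partial correlation is full-order: the gene–gene correlation matrix R is
shrunk toward the identity, R* = (1−λ)R + λI, inverted, and the precision
entries rescaled to partial correlations. λ comes from the analytic
(Schäfer–Strimmer-style) ratio of summed estimated variances of the sample
correlations to their summed squares, clipped to [0, 1]; it can be fixed or
disabled (`shrinkage=None`, which raises on singular R with a message
naming the remedy). With two genes the conditioning set is empty and the
plain correlation is returned. The first-order closed form
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) is kept in the test suite as an
independent oracle for 3-gene systems.

Matrix agreement is the Pearson correlation of two matrices' common
off-diagonal scored pairs; threshold overlap counts pairs at or above each
matrix's own mean + k·sd cut (k = 2 by default) in both matrices.

## Phylogenetic profiles

Ortholog tables carry a confidence score in [0, 1] (0 = absent) and a
cluster bit score per gene × species. Presence is score > 0. Agreement is
the fraction of species where both genes are present or both absent;
Pearson operates on the binary profiles; mutual information is the plug-in
estimate on the empirical 2×2 joint in bits (log2, configurable base;
0·log 0 = 0; no bias correction — the tables are 2×2 and the estimator
deliberately simple). The "bits" recipe correlates score × bit-score
vectors, retaining confidence information instead of binarising. Genes
absent everywhere are dropped with a warning; a reference species that is
trivially present for every gene can be removed via `exclude_species`
(the synthetic worlds have no such species, so the default is an empty
list). Within fixed marginals and correlation sign, MI is a monotone
function of r² on the 2×2 table; across different marginals it is not, and
the test suite asserts exactly the version that is true.

## Colocalization

Records are filtered per source: HPA needs reliability High, Medium, or
Supportive; GO needs evidence in {EXP, IDA, IPI, IGI, IMP, IEP, TAS};
LocDB primary and secondary are both kept. Surviving terms are pooled per
protein as a union across sources (the most inclusive conflict resolution).
A pair is NA if either protein has no terms; CO if the term sets share a
term or a common non-root ancestor (sources annotate at different
granularity); AT if one side is extracellular and the other cytosolic, or
one in an organelle and the other cytosolic — compartments that merge upon
secretion or organelle rupture; else NC. Precedence NA > CO > AT > NC: a
multi-compartment protein can satisfy both CO and AT, and sharing an
annotation is the stronger statement. The compartment model (category sets
and ancestry) ships as an editable table, not hard-coded ontology ids.

## Evaluation

ROC AUC uses the Mann–Whitney rank formulation, so ties earn ½ credit
exactly. Because TNs outnumber TPs by more than an order of magnitude, the
headline statistic is the distribution of AUC over repeated balanced
subsamples: restrict to pairs scoreable in the matrix, then repeatedly draw
(without replacement) as many TNs as there are scoreable TPs. The scoreable
restriction is surfaced as `n_tp_used` — matrices that cannot score every
annotated pair evaluate against fewer TPs, and the number is reported
rather than hidden. One seeded RNG drives all repeats sequentially and is
recorded in the output.

Top-fraction accuracy fixes the positive-prediction threshold at the
(1 − fraction) quantile of the whole scoreable candidate universe (not per
subsample): per balanced subsample, accuracy is (TPs at/above threshold +
TNs below) / (2·n_tp). Ties at the cut go to the positive side.

The matrix-combination classifier turns each gold pair into a feature
vector of its per-matrix scores (missing values median-imputed per
feature), draws a stratified 60/40 train/test split, and reports test-set
AUC. The shipped presets are a random forest with `max_features=2` and an
RBF SVM with C = 0.1 and kernel width 0.2 (sklearn's `gamma` equals the
kernlab-style sigma in exp(−σ‖x−y‖²)); any estimator with a sklearn-like
`fit`/`predict_proba` contract can be plugged in.

## Prediction cascade

Stages run in order: coexpression strictly greater than the threshold
(0.6 by default; missing scores never pass an evidence filter),
localization class in {CO, AT, NA} (dropping every unannotated pair would
gut the search space, so NA passes by default), and enzymatic family
precedent (clause i: the inhibitor blocks some protease of the candidate's
family; clause ii: the protease is blocked by some inhibitor of the
candidate's family; the firing clause is recorded per pair). Localization
and family filters are per-pair predicates and therefore commute; the
implementation's fixed order is for accounting only. Known TPs are kept in
the stage table's counts but excluded from the novel-prediction list.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes, not
transcriptome realism. Defaults are the study conditions used throughout
the tests:

| knob | default | rationale |
|---|---|---|
| protease classes × per class | 5 × 20 | the five catalytic classes; 100 proteases |
| inhibitor families × per family | 6 × 5 | serpin/cystatin/TIMP/Kunitz-like commitments plus one broad (macroglobulin-like) family; 30 inhibitors |
| n_true_inhibitions | 60 | ~2 annotated targets per inhibitor, sparse against 3,000 candidate pairs |
| tissues × samples | 20 × 10 | enough samples (200) for stable correlation, enough tissues for the two archetypes |
| planted_rho | 0.9 | strong planted signal, separable from the null at n = 200 |
| frac_coexpressed_truth | 0.5 | half of truths carry expression signal; the monotone dial {0, 0.5, 1} brackets it |
| expression_noise_sd | 0.5 | ~3-fold lognormal scatter, typical between-sample spread |
| n_species / phylo_flip_rate | 162 / 0.1 | ortholog panel size of the emulated database; mild profile divergence |
| localization_missing_rate | 0.6 | missing annotation dominates real localization data |
| ppi_recall / spurious edges | 0.27 / 200 | about a quarter of true inhibitions visible as physical edges, plus noise |

Log10 expression is a per-gene tissue baseline plus Gaussian noise.
Housekeeping genes draw a flat baseline in Uniform(0.5, 1.5) (≈3–30
RPKM); tissue-specific genes are high (Uniform(1.0, 2.0)) in one or two
home tissues and at the detection floor (10⁻²) elsewhere. Planted pairs
share a latent factor with loading √ρ, giving log-scale population
correlation exactly `planted_rho`; pairs sharing a gene are merged into
connected components sharing one factor, since a gene cannot carry two
independent high loadings, so every within-component pair attains ρ.
Planted genes are set to housekeeping baselines so the tissue profile does
not perturb the planted correlation. Consequences worth knowing: truths
connected through a planted chain are also correlated, and with a
broad-spectrum inhibitor family in the catalog an occasional TN pair can
land inside a planted component — the evaluation tests tolerate this
realistic leakage. Ortholog profiles work the same way at the
presence/absence level: each true-pair component shares a random base
profile, each member flips bits independently at `phylo_flip_rate`.
Localization, missingness, and PPI recall knobs produce exact
(round-half-up) counts so tests can assert them sharply.

Every sub-generator derives its own RNG substream from the single config
seed with a fixed component key, so `generate_world` and standalone
sub-generator calls are bit-identical and reproducible.

What passing tests do *not* show about real data: no length/GC bias or
count-level noise in expression, no phylogenetic tree structure (species
are i.i.d.), no correlation between evidence layers beyond the shared
truth, and identifiers are schematic. Signal-recovery results on these
worlds demonstrate that the machinery measures what it claims, not that
real coexpression predicts real inhibition.

## Numerical choices and degenerate inputs

Correlation scores are clipped to [−1, 1]; zero-variance inputs yield
missing scores (with warnings) rather than errors wherever a matrix can
still be useful, and errors where it cannot (all-constant agreement
vectors, fewer than 3 samples, fewer than 2 species). Division-by-zero
ratio cells print "NA". Quantile thresholds use linear interpolation
(numpy default); membership at the cut is inclusive. Problem sizes in the
test suite (worlds of 130 genes × 200 samples, 20-seed batches, 50–200
subsample repeats) keep the full suite under a minute while leaving the
stochastic assertions comfortably inside their sampling bands.

## Known limitations

Partial correlation shrinks toward the identity on the correlation scale
only; no positive-definiteness repair beyond shrinkage is attempted. The
MI estimator is intentionally uncorrected and will overestimate
independence MI on very small panels. The localization generator assigns
compartments uniformly rather than by protein role, so synthetic AT/CO
base rates are not calibrated to real annotation biases. The cascade
treats the coexpression matrix as a single designated input; combining
multiple matrices happens upstream (element-wise max or the classifier),
not inside the cascade.
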