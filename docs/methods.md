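# Methods

## Problem and pipeline

Patients withdrawing from life-sustaining treatment in the ICU often
receive specialist palliative care late or not at all. One way to find
*triggers* — signals that a palliative consultation should be
considered — is to mine the medications documented in clinical
free-text notes: drugs prescribed much more often to patients whose
palliative referral came early (relative to death) are candidate
referral triggers.

The pipeline has five stages:

1. **Lexicon.** A validated surface-form → canonical map over drug
   names (brand names and abbreviations merged into generics, e.g.
   Diflucan → fluconazole). Matching is exact and case-insensitive;
   ambiguous synonyms are a hard load error because a silently
   mis-canonicalized surface form corrupts every downstream count.
   Hyphen and space are equivalent separators in multi-word names
   (piperacillin-tazobactam ≡ piperacillin tazobactam).
2. **Extraction.** Notes are tokenized (case-folded, punctuation
   split, hyphens kept inside tokens, no stemming) and scanned with a
   longest-match-first, non-overlapping matcher, so a compound name
   never also counts as its prefix. All of a patient's notes are
   pooled into one row of the document-term matrix **A** (patients ×
   canonical terms). The default mode is **binary** (presence per
   patient); `count` mode (total mentions) is available. Never-seen
   terms are dropped and columns are sorted, so the layout is
   deterministic.
3. **Cohort split.** The referral-to-death interval is the whole-day
   difference between first palliative referral and death. The cohort
   is split at the median interval; ties at the threshold go to the
   *early integration* group (the "≥ median" rule). For even cohort
   sizes the default threshold is the lower median — an attained day
   count, so "≥ threshold" always references a realizable value — with
   the midpoint rule selectable.
4. **Trigger index.** For each term, with early/late group word
   frequencies `f_e`, `f_l`:

       difference = f_e − f_l
       PTI        = f_e × difference

   Zero `f_e` or zero difference gives PTI = 0. Negative differences
   are kept (negative PTI) rather than clamped; the top-k report is
   unaffected and the sign is informative. Ranks are competition
   ("min") ranks, so ties share a rank. Frequencies are compared raw,
   as group sizes from a median split are nearly equal; a per-capita
   variant (`normalize=True`) exists as an explicitly marked
   extension.
5. **Networks.** Per group, the co-occurrence matrix is the exact
   integer product C = A′A of that group's matrix. Edge weights
   ("co-correlation") default to the **phi coefficient** — the Pearson
   correlation of two binary indicator columns, computed from the 2×2
   contingency table — because the reported edge values live in a
   correlation-like range; cosine and Jaccard are selectable and the
   output labels the method. Nodes are terms at or above a group
   frequency cut-off (defaults 3 early / 2 late), edges are defined
   co-correlations ≥ 0.5; zero-variance columns have undefined phi and
   contribute no edge (not an edge of 0). Isolated nodes are kept.

## Statistical properties of the PTI worth knowing

- PTI is quadratic in a common frequency scale: doubling both group
  frequencies quadruples it.
- Under a null in which a drug has equal prescription probability in
  both groups, PTI is *not* mean-zero: E[PTI] = E[f_e]·E[diff] +
  Cov(f_e, f_e − f_l) = Var(f_e) > 0, since `f_e` appears in both
  factors. The bias (≈ n·p(1−p)) is small relative to the per-cohort
  sampling spread, which is what the null-configuration test asserts,
  but PTI values should not be read as centered effect sizes.
- No null distribution, p-values or confidence intervals are attached:
  the index is a screening heuristic, and no inferential procedure is
  defined for it here.
- phi between *rare* binary indicators is unstable: with document
  frequencies near the node cut-off, an overlap of two patients can
  already push phi past 0.5. The `min_frequency` filter mitigates but
  does not remove this; edges between low-frequency terms deserve
  skepticism.

## Synthetic cohort generator

No patient data ships with the package; the generator produces
cohorts with planted structure so every stage is testable end to end.

- **Latent groups.** Each patient is latent-early or latent-late with
  probability ½. Intervals are log-normal (right-skewed, like real
  referral-to-death intervals): the two latent groups' medians are
  placed symmetrically around `median_interval_days` on the log scale
  (factor `group_separation`, default 2.2; log-sigma
  `interval_dispersion`, default 0.8), so the mixture median equals
  the target. The *observable* split is by realized median, so latent
  and observed groups deliberately disagree for a configurable
  fraction of patients (~16% at the defaults) — the pipeline is
  exercised under realistic group impurity.
- **Drug sets.** Per drug, independent Bernoulli draws with
  group-specific probabilities. The default profiles encode the
  reference frequency table (frequency / group size at sizes 61 and
  58) plus background ICU agents, so a default simulation reproduces
  the qualitative structure of the motivating analysis (cefepime at
  the top of the ranking, a micafungin–voriconazole early-group
  edge). Co-prescription pairs add a joint boost: with probability
  `joint_boost` a patient receives both drugs of the pair.
- **Notes.** 2–4 notes per patient; each true drug is written into at
  least one note, as a brand synonym with probability
  `synonym_usage_rate` (default 0.2); the rest is filler from a fixed
  non-drug vocabulary with random punctuation and capitalization to
  exercise the tokenizer. The generator makes no attempt at realistic
  clinical prose, negation ("no morphine given"), medication-list
  section structure, or non-English text — tests passing on synthetic
  notes therefore certify the counting pipeline, not clinical NLP
  accuracy on real EHR narratives.
- Everything derives from one integer seed; a fixed seed reproduces
  the cohort byte for byte.

## Calibration of the recovery tests

Two stochastic tests assert recovery of planted structure across 50
seeded cohorts of 120 patients, with margins established by Monte
Carlo before the tests were frozen:

- **Drug ranking.** One drug planted at p_early 0.6 vs p_late 0.3
  among 30 null drugs at p 0.15 must reach PTI rank 1 in ≥ 90% of
  seeds (observed 98% in calibration). These tests use
  `group_separation=4.0` (≈96% latent/split agreement): they test
  recovery of planted contrast *through* the median split, not the
  split's purity — at the study-emulating default separation the
  same contrast reaches rank 1 in only ~70% of seeds, which measures
  impurity dilution rather than the ranking statistic.
- **Edge recovery.** A pair at base prevalence 0.05 with joint boost
  0.35 must appear as an early-group edge (phi ≥ 0.5, min frequency
  3) in ≥ 90% of seeds (observed 100%), while 30 independent null
  drugs at p 0.3 must produce no null–null edge in ≥ 90% (observed
  96%). The null drugs here are *common* by design: the rare-indicator
  instability of phi described above makes spurious strong edges
  between rare nulls an expected phenomenon, not a defect under test.

## Numerical and design choices

- Medians and ranks: lower median for even n (configurable);
  competition ranks via `scipy.stats.rankdata(method="min")`;
  table sort is PTI-descending with alphabetical tie-break
  (stable mergesort), so output ordering is deterministic.
- Percentages in cohort summaries use decimal half-up rounding to one
  decimal (72/119 → 60.5), not banker's rounding.
- C = A′A is computed in exact integer arithmetic.
- phi is computed from the 2×2 contingency counts, not a generic
  correlation routine, so the undefined (zero-variance) case is
  explicit: NaN, flagged, excluded from edges.
- Degenerate inputs: an empty note yields a patient row of width 0
  after zero-column dropping; a cohort needs ≥ 2 patients to split;
  an empty lexicon or note file is an error naming the stage.
- Determinism: pipeline outputs carry a config fingerprint; rerunning
  the same config on the same inputs is byte-identical.

## Problem sizes used in the shipped checks

Unit and property tests run on matrices up to 30 patients × 15 terms;
the recovery tests use 50 cohorts of 120 patients and ~31 drugs; the
parameter-recovery rank-correlation check uses one 500-patient cohort
(Spearman ρ observed 0.86 against the planted enrichment ordering
p_early·(p_early − p_late)). The reproduction script runs the
reference frequency table (11 terms), a 119-patient default synthetic
cohort, and 20-seed recovery rates.

## Known limitations

- The matcher is exact: misspellings, inflections and abbreviations
  are found only if present in the lexicon; no negation or section
  awareness, so "morphine declined" counts as a mention.
- Binary vs count mode is the analysis's most consequential ambiguity;
  binary is the default (patient-level document frequency) and both
  are exposed.
- PTI has the positive null bias derived above and no attached
  inference; it ranks candidates, it does not test them.
- The synthetic generator validates mechanics, not clinical validity;
  findings on real EHR data additionally depend on documentation
  practice (e.g. longer admissions mechanically accumulate more
  distinct drug mentions).
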