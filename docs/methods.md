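# Methods

## The appraisal model

The package evaluates individual in vitro toxicity studies along two
separate axes. **Reliability** is an intrinsic property of the study and
is split into reporting quality (RQ: how completely design, conduct and
results are reported) and methodological quality (MQ: whether the design
and methods are sound, appropriate and sensitive). **Relevance** is
context-dependent: whether the tested substance, test system, endpoint
and concentrations are fit for the specific assessment question. The two
axes are never aggregated; a perfectly reliable study can be irrelevant
to a given question and vice versa.

Reliability is judged criterion by criterion on a four-category scale —
fulfilled (F), partially fulfilled (PF), not fulfilled (NF), not
determined (ND). ND is a *judgment* that the report contains too little
information to decide; it is distinct from *removing* a criterion as not
applicable (NA), which excludes it from every computation. Relevance is
judged per item as directly (DR), indirectly (IR) or not relevant (NR),
or ND; items can be neither weighted nor removed.

## The weighted score

For a section with retained criteria i, weights w_i and ratings r_i:

    score = ( Σ_{r_i=F} w_i + 0.5 · Σ_{r_i=PF} w_i ) / Σ_i w_i × 100

The unweighted formula operates on counts; weighting is specified in
prose (each criterion is multiplied by its weight). The weights are
applied in both numerator and denominator — the only reading under which
an all-fulfilled evaluation scores 100 for any weight assignment. The
score is bounded in [0, 100]; NF and ND contribute identically (zero to
the numerator, full weight to the denominator), so a poorly reported
study is penalised the same whether a criterion fails or cannot be
judged. Upgrading one criterion NF→PF or PF→F raises the score by
exactly 50·w_i/Σw.

Parameters and defaults:

* **weight** — per-criterion multiplier, continuous in [1.0, 1.5],
  default 1.0. The instrument describes the range without a step, so any
  intermediate value is accepted.
* **include_open_questions** — default `True`. The two free-form "other
  aspects" entries (RQ24, MQ16) are counted among the 24/16 criteria and
  are therefore score-eligible by default; because their question form
  makes F/NF semantics debatable, `False` excludes them from both
  numerator and denominator. This was a genuinely open design point; the
  default follows the criterion counts.
* Unrated retained criteria are an **error**, never silently ND: ND is
  an explicit judgment, and conflating "not yet judged" with "judged
  undeterminable" would corrupt both score and profile.

The colour profile reports, per evaluation domain, the weighted fraction
of retained criteria in each category; fractions per domain sum to 1 and
a criterion with increased weight occupies proportionally more area. A
domain whose criteria were all removed is omitted from the bars and
listed in `omitted_domains`. The relevance profile is the equal-weight
pie over the four items (ND shown grey, like the reliability charts).
Scores are reported to one decimal in human-readable output and at full
precision in machine formats.

## Multi-rater variability

Evaluations of one study by several raters consolidate into a
rater × criterion token matrix; removed criteria appear as NA and leave
both numerator and denominator of every proportion. Agreement per
criterion is summarised by two signals: the number of distinct
categories observed (k) and the share of raters per category, in
particular the modal share p_max. ND counts as an ordinary category.
Ties for the modal category are broken by the fixed order F > PF > NF >
ND (DR > IR > NR > ND); the tie-break affects only the modal label,
never p_max or the classification.

Classification rules (all thresholds configurable via
`DecisionRuleConfig`, echoed into output metadata):

| class      | condition (defaults)                                |
|------------|-----------------------------------------------------|
| consensus  | p_max = 1 (unanimity over retained raters)          |
| low        | 0.8 ≤ p_max < 1                                     |
| high       | p_max < 0.6, or k ≥ 3 and p_max < 0.8               |
| moderate   | otherwise (0.6 ≤ p_max < 0.8 with k ≤ 2)            |

The consensus and low bands are fixed by the instrument's published
decision rules. The high-variability branch reconstructs an unpublished
decision tree from its two stated signals (category count and
percentages) and the stated low band; the exact original cut-offs were
chosen qualitatively, not statistically, so the defaults here are a
documented, configurable reconstruction rather than a transcription.
The *moderate* class is this package's addition: the published low and
high rules do not partition the space, and leaving the gap implicit
would make the classification non-total. Criteria retaining fewer than
`min_raters` (default 2) ratings are marked unclassifiable. Consensus is
defined over retained raters, so a criterion removed by some raters can
still reach consensus among the rest.

Prioritization unions the per-study classifications: a criterion is
flagged for refinement when classified high in at least one study;
criteria at consensus or low variability everywhere are not flagged.
Survey-style summaries use integer percentages rounded half away from
zero, which reproduces every printed count/percent pair exactly.

## Synthetic data

The generator emulates the *structure* of expert rating panels — a token
per rater and criterion, with optional removals — not expert behaviour.
Cells are independent across raters and criteria: first a removal draw
(reliability sections only, probability `removal_probability`, default
0), then a category from the criterion's probability vector. Draws use
NumPy's PCG64 with a mandatory seed; identical seeds give identical
matrices on any platform. An optional per-rater leniency hook (off by
default) mixes a rater's distribution toward the most or least
favourable category, as a minimal stand-in for rater effects.

What the independence assumption leaves out — and what passing tests
therefore do not show about real panels: correlated rater severity,
criterion difficulty structure, domain-level correlations, and the
dependence between a rater's removals and their other ratings. Tests on
synthetic panels validate the *machinery* (counting, classification,
thresholds), not any claim about real inter-expert agreement.

Evaluation presets (`well_reported`, `poorly_reported`, `mixed`) draw
complete single-study evaluations with rating distributions skewed
toward F, toward NF/ND, or balanced; they exist to exercise scoring and
reporting at realistic score levels (expected scores 80, 17.5 and 50 at
default weights).

## Numerical choices

* Scores and fractions are plain float arithmetic; equality checks in
  tests use 1e-9 absolute tolerance. Profile fractions per domain sum to
  1 within 1e-9.
* Consensus requires p_max exactly 1; with n ≤ a few dozen raters p_max
  is a small-integer ratio, so no epsilon is needed.
* Percent summaries round half away from zero using exact `Fraction`
  arithmetic, avoiding binary-float half-point artifacts.
* Degenerate inputs: scoring with every criterion removed raises rather
  than returning 0/0; an all-NA matrix column yields an n_retained = 0
  marker with no proportions.
* Problem sizes in the test suite (500-rater panels, 200 replicates,
  exhaustive 5-rater token enumeration) were chosen as the smallest
  panels at which the binomial noise in p_max is negligible relative to
  the rule thresholds (sd ≈ 0.013 at p = 0.9, n = 500, against a 0.2-wide
  band).

## File formats

JSON is the canonical machine format for catalogs, evaluations and
classifications. The evaluation CSV dialect has columns
`id, section, rating, weight, removed, justification, comment` with
study metadata and section scores as leading `# key=value` comment
lines; rating tokens are exactly F/PF/NF/ND (reliability) and
DR/IR/NR/ND (relevance) — spelled-out labels are rejected with the
offending row named. Excel export (openpyxl) embeds the stacked-bar and
pie charts. Scores embedded in any format are recomputed on import; a
mismatch raises a tamper warning carrying both values. Colour mapping is
fixed: green `#2ca02c` (F/DR), yellow `#ffd92f` (PF/IR), red `#d62728`
(NF/NR), grey `#bfbfbf` (ND).

## Known limitations

* The bundled catalog carries no per-criterion guidance text (the
  instrument's guidance is distributed separately online); the field
  exists and is empty.
* The high-variability thresholds are a reconstruction (see above);
  analyses intended to match a specific configuration should pin
  `DecisionRuleConfig` explicitly.
* No chance-corrected agreement statistics (Fleiss' κ, Krippendorff's
  α): the semi-quantitative rule-based classification is the method
  implemented; chance correction would be a separate extension.
* Scores of the two reliability sections are deliberately never
  combined, and no overall "reliability number" is offered.
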