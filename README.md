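# scirap

Structured evaluation of the **reliability** and **relevance** of in vitro
toxicity studies, for regulatory hazard and risk assessors, systematic
reviewers and researchers appraising non-guideline studies as part of a
weight-of-evidence analysis.

The package implements the SciRAP in vitro instrument (version 2.0) as an
offline library and CLI:

* a versioned **criteria catalog** — 24 reporting-quality (RQ) criteria,
  16 methodological-quality (MQ) criteria and 4 relevance items, grouped
  by evaluation domain (test compound and controls, test system,
  administration of test compound, data collection and analysis, and for
  RQ also funding and competing interests);
* **study evaluation** state: each reliability criterion is rated
  fulfilled (F), partially fulfilled (PF), not fulfilled (NF) or not
  determined (ND); criteria may be weighted in [1.0, 1.5] or removed as
  not applicable; relevance items are rated directly (DR), indirectly
  (IR) or not relevant (NR), or ND, and can be neither weighted nor
  removed;
* the **weighted score** per section,

      score = (F + 0.5 · PF) / T × 100,

  where F and PF are the weighted sums over fulfilled and partially
  fulfilled criteria and T is the total weight of retained criteria
  (0 = all not fulfilled, 100 = all fulfilled; NF and ND contribute
  identically);
* the **colour profile**: per-domain stacked bars (RQ/MQ) and the
  relevance pie, with weighted criteria occupying proportionally larger
  area;
* report **export/import** (JSON canonical; CSV and Excel with embedded
  charts), with embedded scores recomputed on import;
* **multi-rater analysis**: consolidation of many evaluations into a
  rater × criterion matrix, per-criterion agreement (category count k
  and modal share p_max over non-removed ratings), classification of
  inter-rater variability (consensus / low / moderate / high) by
  configurable threshold rules, and cross-study prioritization of
  high-variability criteria;
* a seeded **synthetic generator** for evaluations and rater panels with
  controlled agreement, so the whole pipeline is testable without any
  proprietary expert data.

## Worked example

```python
from scirap import StudyEvaluation, compute_score, compute_colour_profile, load_catalog

cat = load_catalog("scirap-invitro-2.0")
ev = StudyEvaluation(cat, study_label="Study 1", evaluator="expert-a")
for c in cat.criteria:
    ev.set_rating(c.id, "F")
ev.set_rating("RQ02", "PF")      # purity only partially reported
ev.set_rating("RQ08", "ND")      # metabolic competence not determinable
ev.remove_criterion("RQ09", "study used primary cells, not a cell line")
ev.set_weight("MQ14", 1.5)       # cytotoxicity control deemed critical
ev.set_rating("MQ14", "NF")
for item in cat.relevance_items:
    ev.set_relevance_rating(item.id, "DR")
ev.set_relevance_rating("REL4", "IR")

rq = compute_score(ev, "RQ")
mq = compute_score(ev, "MQ")
print(f"RQ score: {rq.score:.1f}  (F={rq.F}, PF={rq.PF}, T={rq.T})")
print(f"MQ score: {mq.score:.1f}  (F={mq.F}, PF={mq.PF}, T={mq.T})")
print("relevance pie:", compute_colour_profile(ev, "REL").overall)
```

prints

```
RQ score: 93.5  (F=21.0, PF=1.0, T=23.0)
MQ score: 90.9  (F=15.0, PF=0, T=16.5)
relevance pie: {'DR': 0.75, 'IR': 0.25}
```

The RQ score is (21 + 0.5·1)/23 × 100: removing RQ09 drops T from 24 to
23; the ND rating on RQ08 counts zero, like an NF would. The MQ score
shows the weight at work: the not-fulfilled cytotoxicity criterion enters
the denominator at weight 1.5, so 15/16.5 × 100 ≈ 90.9. Relevance has no
numeric score — three items directly relevant and one indirectly
relevant give the 75%/25% pie.

The same flows are available from the shell:

```sh
scirap synth evaluation --preset mixed --seed 3 --out demo.json
scirap score demo.json            # RQ score: 58.3 / MQ score: 43.8
scirap render demo.json --section RQ --out profile.svg
scirap synth panel --section RQ --raters 31 --seed 7 --out matrix.csv
scirap classify matrix.csv --out classes.json --json
scirap prioritize classes.json --out priorities.csv
```

Classification output embeds the tool version and the decision-rule
thresholds that produced it.

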