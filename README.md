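# obturator-cbr

Case-based reasoning (CBR) retrieval of definitive **obturator prosthesis**
designs for maxillectomy patients.

After a maxillectomy, the design of the removable obturator that seals the
defect depends on many interacting features of the oral condition: the
Aramany class of the defect (I–VI), the abutment teeth bordering it and
their condition, bounded edentulous spaces, the size of the oronasal
connection, and so on.  This package supports the clinician the way an
experienced colleague would — by recalling previously treated cases with a
similar oral condition and showing the designs that worked for them:

1. **Describe the new case** through a dynamically branching questionnaire.
   The declared Aramany class selects the question set; earlier answers
   drive skip logic (e.g. answering *no bounded spaces* suppresses the
   question about their location; a Class VI case answers the abutment
   questions once per side of the arch).
2. **Retrieve similar stored cases.**  Every stored case of the *same
   Aramany class* is scored with a weighted keyword-match confidence

   ```
   confidence(q, c) = Σ_{k ∈ M} w_k / Σ_{k ∈ K} w_k
   ```

   where `K` is the set of attributes present in both records, `M ⊆ K` the
   attributes on which they agree, and `w_k` the attribute weights.
   Clinically secondary attributes (remaining-molar count, both-premolars
   flag) carry a weight equal to 5% of the comparable total, so a sole
   disagreement there costs exactly 0.05.  The top *k* (default 5) cases
   are returned in descending confidence (ties broken by case ID) together
   with the shared keywords and the file paths of the stored design images.
   A result is flagged *eligible* when its confidence is strictly above
   0.90.
3. **Evaluate retrieval quality** against externally supplied relevance
   labels (clinician judgments): per-case precision@k curves with
   across-case medians, min/max/median summaries, and Spearman's ρ between
   the mean top-k confidence and the number of correct designs per case.

No clinical data are included.  A synthetic generator produces schema-valid
case bases (209 cases by default, skewed toward Aramany Classes I and II),
perturbation-controlled test queries and logistic-link relevance labels so
the entire pipeline runs end to end.

## Worked example

```sh
# a synthetic case base of 209 cases
obturator-cbr synth --n 209 --seed 42 --out cases.csv

# retrieve designs for a new Class II case described by a JSON transcript
obturator-cbr retrieve --casebase cases.csv --answers answers.json \
    --top-k 5 --out report.json
```

with `answers.json` holding the ordered interview transcript
`[["aramany_class", "II"], ["nearest_abutment", "15"], ["last_tooth", "26"],
["defect_extension", "one_quadrant"], …]` this prints:

```
Top 5 matching Class II designs (k=5)
  #1  C0011  confidence=1.000  [eligible]
      shared: nearest_abutment, last_tooth, defect_extension, abutment_condition, bounded_space_count, bounded_space_location, bounded_space_distribution, oronasal_connection, defect_side_remaining_teeth, remaining_molar_count
      media:  media/C0011_design.png
  #2  C0126  confidence=0.556  [below threshold]
      shared: defect_extension, abutment_condition, bounded_space_count, bounded_space_distribution, defect_side_remaining_teeth
      media:  media/C0126_design.png
  ...
```

The query here reproduces stored case `C0011` exactly, so that case matches
on every attribute (confidence 1.0, eligible); the runner-up agrees on 5 of
9 comparable attributes weighted to 0.556 and falls below the 0.90
eligibility threshold.  Adding `--open` opens the matched design images in
the OS viewer.

A full synthetic evaluation round:

```sh
obturator-cbr synth-eval --casebase cases.csv --n-tests 33 --seed 7 --out eval/
obturator-cbr evaluate --confidences eval/confidences.json \
    --labels eval/labels.csv --top-k 5 --curve-k 15 --out metrics/
# n=33  Spearman rho=0.690 (p=8.88e-06); median precision@5=0.600
```

`metrics/` then contains `precision_curve.csv` (per-case and median
precision at k = 1..15) and `correlation.json` with the ρ above plus
min/max/median summaries of the mean top-5 confidences and correct-design
counts.  The positive, highly significant ρ says that test cases whose
retrieved designs scored higher confidence also collected more
(synthetically) relevant designs — the association the confidence score is
meant to carry.

The same functionality is available as a library:

```python
from obturator_cbr import (GeneratorConfig, generate_casebase,
                           replay_transcript, retrieve, flag_eligible)

casebase = generate_casebase(GeneratorConfig(n_cases=209, seed=42))
query = replay_transcript([("aramany_class", "I"), ...])
report = flag_eligible(retrieve(query, casebase, k=5))
```

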