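# sdctab

Statistical disclosure control for tabular microdata. `sdctab` anonymizes a
table of personal records — a hospital admission list, a census extract — so
it can be shared without re-identifying anyone, and audits the privacy level
any table already achieves.

It is aimed at researchers and data stewards who need to publish
person-level CSV data under privacy regulations and want the whole process
(roles, hierarchies, privacy model, suppression budget) to run locally as a
Python library or a small CLI, with nothing uploaded anywhere.

## The model

Columns are classified into four roles: **identifiers** (name, patient ID —
replaced by `*`), **quasi-identifiers** (age, gender, city — attributes that
re-identify in combination), one **sensitive attribute** (the value to be
protected, e.g. disease) and **insensitive** columns (passed through).

An **equivalence class** (EC) is a maximal set of rows identical on every
quasi-identifier. Each quasi-identifier may carry a **generalization
hierarchy** h₁…hₙ — an ordered chain of total value mappings that coarsen it
step by step (ages → 5-year intervals → 10-year intervals; cities → `*`).
Given a privacy requirement and a record-suppression budget (a percentage of
the original rows that may be deleted, always as whole equivalence classes),
the engine searches the lattice of per-QI generalization levels for a
**transformation vector** [j₁,…,j_m] under which the requirement holds.

Nine privacy models are supported. With p(s|EC) the frequency of sensitive
value s inside a class and q(s) its frequency over all retained rows:

| model | requirement on every EC |
|---|---|
| k-anonymity | \|EC\| ≥ k |
| (α,k)-anonymity | \|EC\| ≥ k and p(s\|EC) ≤ α |
| ℓ-diversity | ≥ ℓ distinct sensitive values |
| entropy ℓ-diversity | −Σ p ln p ≥ ln ℓ |
| recursive (c,ℓ)-diversity | r₁ < c·(r_ℓ+…+r_m) for descending counts rᵢ |
| t-closeness | EMD(p(·\|EC), q) ≤ t |
| δ-disclosure | \|ln(p/q)\| < δ for every s with p > 0 |
| basic β-likeness | (p−q)/q ≤ β whenever p > q |
| enhanced β-likeness | (p−q)/q ≤ min(β, −ln q) whenever p > q |

Every composite model also enforces k-anonymity (k is always required). The
auditor (`privacy_report` / `sdctab report`) computes the achieved value of
all of these for any table.

## Worked example

The package embeds the classic 13-row hospital table (`sdctab.fixtures`):
name is the identifier; age, gender, city are quasi-identifiers; disease is
sensitive. Hierarchies: 5- and 10-year age intervals over [0, 100), plain
suppression for gender and city.

```python
from sdctab import l_diversity
from sdctab.fixtures import hospital_table, hospital_hierarchies

res = l_diversity(hospital_table(), ["name"], ["age", "gender", "city"],
                  "disease", k=2, l=2, supp=0, hier=hospital_hierarchies())
print("transformation:", list(res.transformation))
print("suppressed:", f"{res.suppressed_fraction:.1f}%")
rep = res.report
print(f"achieved k={rep.k}, l={rep.l}, entropy-l={rep.entropy_l}, "
      f"t={rep.t:.4f}, delta={rep.delta:.4f}, beta={rep.beta_basic:.4f}")
print(res.table.to_pandas().head(4).to_string(index=False))
```

prints

```
transformation: [2, 0, 1]
suppressed: 0.0%
achieved k=3, l=3, entropy-l=3, t=0.2821, delta=0.7732, beta=1.1667
name      age gender city religion disease
   * [20, 30) Female    *    Hindu  Cancer
   * [20, 30)   Male    *    Hindu  Cancer
   * [20, 30)   Male    *    Hindu  Cancer
   * [20, 30)   Male    *    Hindu  Cancer
```

The transformation `[2, 0, 1]` means: age generalized to its level-2
hierarchy (10-year intervals), gender untouched, city suppressed. No rows
needed deleting, and the output in fact achieves k = 3 — each of its three
equivalence classes holds at least three records and at least three distinct
diseases, so an attacker who knows someone's age band, gender and city can
neither single out their record nor infer their diagnosis. The audited
t = 0.2821 is the largest earth-mover's distance between a class's disease
histogram and the table-wide one.

The same run from the shell (hierarchies declared in YAML):

```
sdctab anonymize --input hospital.csv --output anon.csv \
    --method l_diversity --k 2 --l 2 --supp-level 0 \
    --id name --qi age --qi gender --qi city --sa disease \
    --hierarchies hierarchies.yaml --report-json report.json
sdctab report --input anon.csv --qi age --qi gender --qi city --sa disease
```

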