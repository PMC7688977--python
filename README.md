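# fedsurv

Privacy-preserving federated survival analysis for multi-registry cancer
cohorts.

Cancer registries in different jurisdictions often cannot pool patient-level
records: data-protection law restricts moving individual data across borders,
while the scientific questions — do prognostic factors act the same way in
different countries? — need the combined cohort. `fedsurv` answers them
without moving records. Each registry runs a *node* holding its own data; a
central *server* dispatches computing tasks and receives only aggregate
statistics whose dimensions depend on the model size and the event-time
grid, never on how many patients a site holds.

The package was built around a two-registry oral-cavity-cancer use case
(a large East-Asian registry and a smaller European one, sites "TW" and
"NL"), but every component — cohort derivation, the federated estimator, the
interaction tests, the synthetic-data generator — is generic over the model
specification.

## The statistics

**Federated Cox proportional hazards with Breslow ties.** With follow-up
expressed in years to one decimal, events are heavily tied and the Breslow
partial likelihood decomposes over the distinct event times *t₁ < … < t_K*:

```
ll(β) = Σ_k [ βᵀ s_k − d_k · log S0_k(β) ]

d_k  = # events at t_k          s_k  = Σ_{events at t_k} z_i
S0_k = Σ_{i: T_i ≥ t_k} e^{βᵀz_i}      S1_k, S2_k = corresponding z- and zzᵀ-weighted sums
```

Every term is a sum over subjects, hence additive across sites: nodes return
(d, s, S0, S1, S2) on a shared event-time grid, the server sums them and
takes Newton–Raphson steps

```
U(β) = Σ_k [ s_k − d_k S1_k/S0_k ]
I(β) = Σ_k d_k [ S2_k/S0_k − (S1_k/S0_k)(S1_k/S0_k)ᵀ ]
β ← β + I(β)⁻¹ U(β)
```

from β = 0 until the difference between the sums of the previous and updated
hazard ratios, |Σⱼ e^{βⱼ,new} − Σⱼ e^{βⱼ,old}|, is below 10⁻⁸. The fit is
*identical* (to solver precision) to a centralized Breslow Cox fit on the
pooled table — federation changes where the sums are computed, not what is
computed.

**Interaction analysis.** Whether a factor's effect differs between
countries is a likelihood-ratio test between two nested federated fits: main
effects only, versus main effects plus the country×factor product columns;
2·(ll_full − ll_reduced) ~ χ² with one df per interaction column.
Per-country hazard ratios come from coefficient sums
(HR_NL(ℓ) = exp(β_country + β_ℓ + β_country×ℓ)) with delta-method intervals.

**Descriptives.** Frequency tables are assembled from per-node level counts
and compared between countries with Pearson's chi-square (no continuity
correction); means from per-node (sum, count) pairs.

## Worked example

No registry data is distributable, so the package ships a generator that
emulates the two registries (category probabilities proportional to the
published per-registry counts, survival from a proportional-hazards model
with known coefficients — see `docs/methods.md`):

```bash
fedsurv simulate --config sim.yaml --out data --seed 7     # sim.yaml: n: {NL: 1500, TW: 3500}
fedsurv cohort --registry data/registry_NL.csv --country NL --out cohorts/NL.csv
fedsurv cohort --registry data/registry_TW.csv --country TW --out cohorts/TW.csv
fedsurv fit --sites sites.yaml --out fitout                # sites.yaml lists the cohort CSVs
```

which prints `converged in 5 iterations; outputs in fitout` and writes the
hazard-ratio table:

```
variable,level,hr,ci,reference
country,TW,1.00,–,True
country,NL,1.06,0.94–1.20,False
age_cat,lt60,1.00,–,True
age_cat,60_69,1.34,1.23–1.47,False
age_cat,ge70,2.41,2.19–2.66,False
sex,female,1.00,–,True
sex,male,1.27,1.16–1.40,False
...
```

Each row is a hazard ratio against the block's reference level (rendered as
`1.00, –`); e.g. patients ≥ 70 at diagnosis die at 2.4 times the rate of
patients under 60, other factors held fixed — close to the generator's true
value 2.40, as it should be at n = 5,000. `fedsurv study` runs the whole
pipeline (descriptives with chi-square tests, univariable per-site and
combined fits, the 18-column multivariable fit, five country×factor
interaction analyses) and writes a manifest with checksums of every output;
`fedsurv interactions` runs just the interaction stage.

The same can be done in Python:

```python
import fedsurv

cfg = fedsurv.SimConfig(n={"NL": 1500, "TW": 3500}, seed=7)
server = fedsurv.build_federation(fedsurv.generate_cohort(cfg))
fit = fedsurv.fit_federated_cox(server, fedsurv.multivariable_spec())
print(fedsurv.hazard_ratios(fit).head())
```

## What is *not* shared

A node only ever returns: distinct event times (rounded to 0.1 years),
dummy-column sums, per-event-time event counts and covariate sums, and the
risk-set sums S0/S1/S2. Every payload crossing the boundary is written to a
JSON-lines audit log with its array shapes; `audit_payload` /
`FederatedServer.audit_violations` flag any array with a dimension equal to
a site's record count. Production concerns — encryption, authentication
beyond a static token, real transport — are explicitly out of scope; nodes
here are in-process actors behind the same Task/TaskResult contract a
networked deployment would use.
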