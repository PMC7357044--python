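# ogttscan

Mechanistic analysis of oral glucose tolerance tests (OGTT) in rodents:
simulate the glucose response with an extended minimal model, score
parameter sets against group-level data with a variance-weighted
residual, and rank one-parameter-at-a-time hypotheses about which arm of
glucose homeostasis a perturbation (such as perinatal cadmium exposure)
most plausibly hit.

Intended for experimentalists and modellers who have group-mean glucose
curves from rodent OGTTs and want more than an area-under-the-curve
comparison — a ranked shortlist of candidate mechanisms — without
committing to a heavyweight multi-compartment model.

## The model

Bergman's minimal model (MINMOD) describes glucose disappearance after
an *intravenous* bolus with three states. Oral tests need a glucose
input flux and a representation of first-phase insulin secretion, giving
four states — glucose G (mg/dL), insulin-driven withdrawal rate X
(1/min), plasma insulin I (nU/dL), and the readily releasable insulin
pool Is (nU/dL):

    dG/dt  = -p1 (G - Gb) - rCd · X · G + GRA(t)
    dX/dt  = -p2 X + p3 (I - Ib)
    dI/dt  = -n I + γ (G - h) t + p4 · Is
    dIs/dt = -p4 · Is

with GRA(t) = K · N(t; μ=30, σ=35) the Gaussian glucose rate of
appearance, normalised so the whole ingested dose (2 mg/g body mass)
enters the blood volume: K = (m_glc/V_blood) / Φ(μ/σ).

Fit quality against a dataset of mean glucose `x_i` with between-animal
variances `ν_i²` is

    ε(k) = √( Σ_i W_i (x_i − G_sim(t_i; k))² ),   W_i = 1/(ν_i² Σ_j x_j²),

and a *hypothesis scan* refits exactly one parameter per mechanistic
hypothesis (H1.1→rCd, H1.2→p3, H1.3→p2, H2→n, H3.1→γ, H3.2→p4, H3.3→h)
with the rest frozen at control values, ranking hypotheses by ε. A
synthetic-cohort generator (per-animal lognormal parameter variability +
Gaussian measurement noise) provides fully specified test beds, since
real per-timepoint spreads are rarely published.

See `docs/methods.md` for assumptions, defaults and calibration.

## Worked example

Generate a matched pair of 48-animal cohorts — a control and one whose
slow-phase secretion gain γ is reduced to 69.4% — then fit the control
and scan the perturbed cohort:

```python
import ogttscan as og
from ogttscan.scan import fit_control, scan

k    = og.fixtures.get_parameters("PND21")      # published control set
s0   = og.fixtures.get_initial_state("PND21")
phys = og.fixtures.get_physiology("PND21")      # K derived: 3729.87 mg/(dL·min)

spec = og.CohortSpec(params=k, init=s0, phys=phys, seed=1, n_animals=48)
d_ctrl, d_pert = og.generate_perturbed_pair(spec, "H3.1", 0.694,
                                            perturbed_group="exposed")
k_fit = fit_control(d_ctrl, s0, phys, reference=k, seed=1,
                    n_starts=8, n_refine=2, budget=600)
report = scan(k_fit, d_pert, s0, phys)
print(og.io.render_report(report, "markdown"))
```

Output:

```
Dataset: exposed@PND21

| Hypothesis | Parameter | Fitted value | Goodness of fit |
|---|---|---|---|
| No Hyp. | | | 0.008 |
| H3.1 | gamma | 0.0216 | 0.000164 |
| H3.3 | h | 105 | 0.00382 |
| H2 | n | 12.8 | 0.00419 |
| H1.3 | p2 | 0.936 | 0.0047 |
| H1.1 | rCd | 0.627 | 0.00491 |
| H1.2 | p3 | 0.00972 | 0.00491 |
| H3.2 | p4 | 0.0339 | 0.00799 |

Best hypothesis: H3.1
```

Reading it: the unmodified control set scores ε = 0.008 on the exposed
cohort ("No Hyp."). Refitting only γ drops ε fifty-fold to 0.000164 and
lands on γ = 0.0216 — the generating value was 0.031 × 0.694 = 0.0215 —
while every competing single-parameter mechanism stays an order of
magnitude worse. The scan correctly identifies a weakened slow-phase
β-cell response, the mechanism implicated at weaning in
cadmium-exposed litters.

The same operations are exposed on the command line:

```sh
ogttscan synth --spec cohort.yaml --out cohort.csv
ogttscan fit-control --dataset control.csv --age PND21 --out ctrl.json
ogttscan scan --control-params ctrl.json --dataset exposed.csv --out report.json
ogttscan report --report report.json
ogttscan simulate --age PND21 --grid 0:120:1 --out traj.csv
```

All commands are deterministic given their inputs and `--seed`.

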