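# logistic-ism

Logistic-ISM analysis of how public-health staff rate the effectiveness of
emergency drills: chi-square screening and binary logistic regression to find
the factors associated with a low rating, then Interpretive Structural
Modeling (ISM) to arrange those factors into a surface/middle/bottom
influence hierarchy.

## The problem

Centers for disease control run simulated emergency drills (tabletop,
operation-based, functional, comprehensive), and staff rate their overall
effectiveness on a 5-point Likert scale.  In a survey of N = 1,859
disease-control staff in Heilongjiang Province, 53.3% rated effectiveness as
low (score at or below the sample mean of 3.16).  Two questions follow:

1. **Which factors are associated with a low rating?**  Each candidate
   variable is screened with an uncorrected Pearson χ² test of its r×2
   cross-tabulation against the high/low split; screened variables enter a
   joint binary logistic regression

   logit P(low) = β₀ + Σⱼ βⱼ xⱼ,

   where each xⱼ is an adverse-level indicator (no equipment, low training
   quality, ...), so OR = exp(βⱼ) > 1 means the adverse condition raises the
   odds of a low rating.  Wald statistics (β/SE)², 95% intervals
   exp(β ± 1.959964·SE), and a Hosmer–Lemeshow decile calibration check
   complete the model.

2. **How do those factors influence one another?**  The significant factors
   S1…Sk get an expert-elicited binary adjacency matrix R (Rᵢⱼ = 1 iff Sᵢ
   directly affects Sⱼ).  ISM computes the Boolean reachability closure
   M = (R + I)^λ, reads off per-factor reachable sets R(Sᵢ), antecedent sets
   A(Sᵢ) and common sets T(Sᵢ) = R(Sᵢ) ∩ A(Sᵢ), and iteratively extracts the
   factors with R(Sᵢ) ∩ A(Sᵢ) = R(Sᵢ) as successive levels: level 1 is the
   surface (most direct influences), the deepest level holds the root
   drivers.

The raw respondent data were never deposited, so the package ships a seeded
synthetic-survey generator that reproduces the published covariate
prevalences and effect sizes, making every stage testable end to end; the
published aggregate tables (cross-tabulations, adjusted odds ratios, expert
adjacency matrix) are included as typed inputs in
`logistic_ism.datasets`.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
survey (`results/` holds their outputs):

```sh
python analysis/01_simulate_survey.py      # 1,859 respondents, seed 0
python analysis/02_screen_chi_square.py    # chi-square screen at alpha=0.05
python analysis/03_fit_logistic.py         # joint logistic fit + calibration
python analysis/04_ism_hierarchy.py        # ISM on the expert adjacency
python analysis/05_verify_published_tables.py
```

Script 03 prints, for seed 0:

```
fitting 6 screened binary predictors on n = 1859
converged in 5 Newton iterations
Predictor                      Wald        P      OR          95% CI
training_frequency            8.617    0.003   1.345   1.103   1.638
training_quality             44.758   <0.001   1.933   1.593   2.344
equipment_guarantee          91.515   <0.001   2.616   2.148   3.186
leaders_focus                13.491   <0.001   1.448   1.188   1.764
coordination                  5.871    0.015   1.267   1.046   1.534
plan_design_skill            13.103   <0.001   1.506   1.206   1.879

Hosmer-Lemeshow: chi2 = 10.855, df = 8, p = 0.210 (well calibrated)
```

Each fitted odds ratio estimates its generating value (e.g. equipment 2.616
vs the true 2.324, inside sampling error at n = 1,859); the generating odds
ratios are the published adjusted estimates.  At this sample size the two
weakest generating effects sit near the edge of detectability, so which of
the seven reach significance varies across seeds — here the fund-guarantee
factor (true OR 1.407) missed the screen.  Script 04 then structures the
seven published factors with the expert adjacency matrix:

```
Level 1 (surface): S1 (training frequency), S2 (training quality),
                   S5 (leaders' focus), S6 (inter-departmental coordination)
Level 2 (middle):  S4 (equipment and facilities guarantee),
                   S7 (drill plan designing skill)
Level 3 (bottom):  S3 (fund guarantee)
```

i.e. funding is the root driver: it reaches every other factor, while the
surface factors form one mutually reachable group that acts on the rating
directly.  `results/hierarchy.dot` holds the transitively reduced hierarchy
in DOT form.

The same stages are available as a CLI (`drill-ism simulate | screen | fit |
ism | run | render`) and as library calls (`logistic_ism.run_pipeline`).

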