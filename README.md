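# dbstune

Semi-automated optimization of deep brain stimulation (DBS) frequency from
quantified rigidity, with a probit Gaussian-process model of patient
preference.

Programming a DBS system for Parkinson's disease is a slow trial-and-error
search over stimulation parameters, scored by subjective ordinal clinical
ratings. `dbstune` implements an alternative workflow for one parameter
(frequency) and one motor sign (forearm rigidity):

1. **Rigidity quantification.** Torque recorded by a robotic manipulandum
   during imposed ±40° passive forearm rotation is low-pass filtered (20 Hz,
   2-pole Butterworth), rectified and integrated; the slope of this angular
   impulse over a 20 s window after a 5 s warm-up is the *RoMaR* value — a
   single scalar rigidity measure per stimulation setting.
2. **Bayesian optimization.** RoMaR as a function of stimulation frequency
   *x* is modelled as a Gaussian process *f(x) ~ GP(m, k)* with a Matérn
   ν = 3/2 kernel, constant mean *m* frozen at the mean of four seed
   measurements (30, 80, 90, 140 Hz), and hyperparameters (length-constant
   ℓ, signal and noise variances) estimated by marginal likelihood. Eight
   acquisition iterations follow, each testing the frequency maximizing the
   expected improvement u(x) = (f(x⁻) − μ(x))Φ(Z) + σ(x)φ(Z) over the
   incumbent best observation f(x⁻), with an exploration override (ratio
   0.5) and a hard tolerability ceiling. A full session yields 12
   measurements and 11 pairwise preference answers.
3. **Preference learning.** After each measurement the patient answers
   "current or previous setting?". These binary comparisons a ≻ b are
   modelled with a probit GP: latent value *f* with GP prior and likelihood
   Φ((f(a) − f(b))/√2σ), fitted by MAP (damped Newton–Raphson, 25 random
   restarts). The predictive mean k<sup>T</sup>K⁻¹f<sub>MAP</sub> with
   variance k(x,x) − k<sup>T</sup>(K + C⁻¹)⁻¹k locates the preferred
   frequency — typically *below* the rigidity optimum.
4. **Evaluation.** The optimal frequency is the GP-mean argmin; the
   *frequency range* (all frequencies whose predicted rigidity lies within
   one posterior sd of the minimum) quantifies precision. Brute-force
   (10–185 Hz in 5 Hz steps, pseudorandom order), equal-interval and random
   sampling baselines are simulated for efficiency comparison.

Everything runs against a built-in **virtual patient** simulator with a
parameterized ground-truth rigidity curve (10 Hz dip, 20–50 Hz worsening,
steep high-frequency benefit, optional 130–155 Hz bump), Gaussian
measurement noise, a tolerability ceiling, synthetic torque traces and a
probit choice model — so the whole pipeline is testable without clinical
recordings.

## Worked example

```python
import numpy as np
from dbstune import (SessionConfig, profile_ar1, run_session,
                     optimal_frequency, frequency_range,
                     PreferenceGP, KernelParams)

patient = profile_ar1()                       # ceiling 155 Hz
state = run_session(patient, SessionConfig(ceiling=155.0, rng_seed=1))
print(state.model.summary())

grid = np.arange(10.0, 160.0, 5.0)
pred = state.model.predict(grid)
fr = frequency_range(pred)
print(f"optimal frequency : {optimal_frequency(pred):.0f} Hz")
print(f"frequency range   : {fr.width:.0f} Hz")

kernel = KernelParams(nu=1.5, ell=state.model.params.ell, signal_var=1.0)
pgp = PreferenceGP(state.preferences, kernel).fit(restarts=25, seed=1)
print(f"preferred frequency: {pgp.preferred_frequency(grid):.0f} Hz")
```

prints

```
Rigidity GP (Matérn) regression results
===========================================
No. observations                         12
Log marginal likelihood             11.5684
Matérn order nu                         1.5
Length-constant ell (Hz)            59.4708
Signal variance                   0.0435793
Noise variance                   0.00197162
Constant mean (RoMaR)              0.876357
===========================================
optimal frequency : 155 Hz
frequency range   : 5 Hz
preferred frequency: 110 Hz
```

The session finds the rigidity optimum at the tolerability ceiling (155 Hz,
the true argmin of this patient's curve) and pins it down to a 5 Hz range
after only 12 measurements, while the preference model peaks at 110 Hz —
near the lowest frequency delivering ~80 % of the maximal rigidity benefit
(105 Hz for this patient), not at the rigidity optimum.

The same workflow is available from the shell:

```bash
dbstune simulate-patient --profile ar1 --out patient.json
dbstune brute-force --patient patient.json --clinical 125 --rng-seed 1 --out bf.csv
dbstune bayesopt    --patient patient.json --ceiling 155 --rng-seed 1 --out session.json
dbstune preference-fit --session session.json --out pgp.json
dbstune evaluate    --bf bf.csv --session session.json --out report.csv
```

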