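# rivermetab

Estimation of daily stream metabolism — gross primary production (GPP),
ecosystem respiration (ER) and the gas exchange rate coefficient (K600) —
from sub-daily dissolved-oxygen sensor records, for ecosystem ecologists and
biogeochemists working with monitoring-network data (oxygen, temperature and
discharge from stream gages; air pressure and shortwave radiation from
gridded climate products).

## The model

Reach-averaged dissolved oxygen on day *d* at timestep *i* evolves as

    dO(i,d)/dt = GPP_d / z(i,d) · PPFD(i,d) / mean_d(PPFD)
               + ER_d / z(i,d)
               + KO2(i,d) · (Osat(i,d) − O(i,d))

with depth *z* (m), photosynthetic photon flux density *PPFD*, saturation
concentration *Osat*, and KO2 = K600·(Sc_O2/600)^−1/2 from the
temperature-dependent Schmidt number.  The equation is integrated with the
trapezoid rule (the gas-exchange term is linear in O, so the implicit step
solves in closed form).  A state-space error structure carries both iid
process error on each step of the latent O2 state and iid observation
error on each measurement; conditional on the daily parameters the system
is linear-Gaussian, so the latent states are marginalised exactly by a
Kalman filter and an ensemble MCMC samples the daily parameters.

Daily K600 values are partially pooled toward a site-level piecewise-linear
relationship between ln K600 and ln(daily mean discharge), with nodes at
fixed 0.2 natural-log intervals, a random-walk prior (sd 0.1) between
adjacent nodes, and a fitted daily-deviation sd whose half-normal hyperprior
is scaled to 2% of the median K600 from a preliminary unpooled fit.  GPP and
ER carry literature-based normal priors, N(3.1, 6.0) and N(−7.1, 7.1)
g O2 m⁻² d⁻¹.

Around the model sits the full pipeline: forcing derivation (standard-
atmosphere pressure from elevation, Garcia–Gordon O2 solubility with
barometric correction, solar-time conversion, modeled/merged PPFD,
hydraulic-geometry depth and velocity), input assembly (interpolation onto
the O2 timestamps, ≤3 h gap filling, exclusion of days with longer gaps or
nonpositive flow, resolution-chunk splitting), posterior summarisation with
split-Rhat/ESS diagnostics and an automatic longer re-run on
non-convergence, and a Low/Medium/High confidence rating per model.  A
synthetic-site generator with known truth makes every stage testable.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
14-day, 15-minute site (the library calls behind them are shown in each
script):

```bash
python analysis/01_simulate_site.py
python analysis/02_prepare_inputs.py
python analysis/03_fit_metabolism.py
python analysis/04_assess_model.py
```

`03_fit_metabolism.py` prints, for the default site:

```
fitted 14 days in 12 s; key Rhat 1.010; mean acceptance 0.30
       parameter    50%   Rhat    n_eff
sigma_K600_daily 0.1051 1.0102 323.6616
       sigma_obs 0.0501 1.0184 306.8946
      sigma_proc 0.0116 1.0064 309.9459

recovery against truth:
           n_days  bias  rmse  rmse_pct_of_magnitude  coverage_pct
GPP            14  0.00  0.13                   2.53         78.57
ER             14 -0.01  0.17                   2.23         85.71
K600           14  0.06  0.20                   1.91         85.71
```

Posterior medians of daily GPP/ER/K600 land within ~2% of the generator's
truth and the fitted error sds match the injected values (obs 0.05, process
~0.01 mg L⁻¹).  `04_assess_model.py` then rates the model:

```
model synth00_0: Rhat(key)=1.010, K600 range=0.33 d^-1, %GPP<-0.5=0,
%ER>0.5=0 -> confidence High (site minimum High)
```

The same chain is available as a CLI
(`rivermetab simulate|prepare|fit|assess`).

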