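# Methods

## Physical model

The respiratory system is a single passive elastic compartment: alveolar
pressure `p_alv = V/C − P_mus` (volume `V` above the relaxed volume, ml;
compliance `C`, ml/mbar; muscular pressure `P_mus = 0` for a passive
patient) behind a linear airway resistance `R_aw` (mbar·s/L). The
endotracheal tube — with or without an inserted bronchoscope — sits in
series and is nonlinear: its pressure drop follows the Rohrer form
`Δp = k1·V̇ + sign(V̇)·k2·(V̇/V̇₀)²` with `V̇₀ = 1 L/s`. The linear
coefficient `k1` is shared between flow directions; the quadratic
coefficient may differ between inspiration (`k2_insp`) and expiration
(`k2_exp`) because of the compression–expansion asymmetry at the tube tip,
though fitted values rarely differ systematically and the scaling law emits
the symmetric `k2 = 4·k1`.

Geometry enters through a single number, the effective diameter
`D_eff = sqrt(D_tube² − D_scope²)` — the diameter of the circular tube with
the same open cross section as the annulus. The scaling law
`k1(D_eff) = 0.72·(D_eff/10 mm)^β` uses `β = −3.6` for an unobstructed tube
(the flow path includes connector and tracheal-transition losses that
soften the exponent below the turbulent-limit value of −5) and `β = −5`
when a scope is inserted. `D_scope` should be the *measured* shaft
diameter; nominal manufacturer sizes can be ~0.1 mm off, which matters when
quoting effective diameters to one decimal.

Sign convention: inspiratory flow (toward the lung) and inspiratory
pressure drops are positive. Units are fixed package-wide: mbar, L/s, ml,
s, mm.

## Ventilation modes

* **VC** — square inspiratory flow `V_T/T_in` for `T_in` (no
  end-inspiratory pause), passive exhalation against PEEP through the tube
  plus an optional linear expiratory-valve resistance `r_valve` (default 0;
  no published value exists, and the wide-lumen results are insensitive to
  it). The ventilator acts as a flow source, so no pressure ceiling is
  enforced during inspiration; samples whose back-computed airway pressure
  exceeds `p_max` (default 80 mbar) are counted and flagged in the summary.
* **PC** — constant inspiratory airway pressure `PEEP + PS` applied
  instantaneously (ramp time 0 by default; a linear ramp is available);
  passive exhalation as in VC. No inspiratory demand-flow cap is applied.
* **ATC** — an idealised tube-compensating controller: the target tracheal
  pressure rises linearly from PEEP to `PEEP + 10 mbar` over `T_in` and
  falls linearly back over `T_ex`; each step sets
  `V̇ = (p_target − p_alv)/R_aw` and applies
  `p_aw = p_target + Δp_tube(V̇)`, clamped to `p_max` (and to ≥ 0 unless
  sub-atmospheric delivery is allowed, the ATC default); after a clamp the
  flow is re-solved from the clamped pressure. Controller dynamics, sensor
  noise and actuator lag are out of scope. ATC requires `R_aw > 0` (the
  ideal-controller flow is otherwise undefined).

Defaults mirror the bench operating point: `C = 50 ml/mbar`,
`R_aw = 2 mbar·s/L`, `PEEP = 0`, `V_T = 500 ml`, `PS = 10 mbar`,
`T_in = 1.8 s`, `T_ex = 2.2 s` (15 breaths/min).

## Numerics

The nonlinear resistance is algebraic, so the only state variable is the
compartment volume. Flow is obtained in closed form at each sample by
solving the sign-consistent quadratic
`k2·V̇²·sign(V̇) + (k1 + R_series)·V̇ = Δp` (the root formula is written in
the cancellation-safe form `2|Δp| / (√(b² + 4a|Δp|) + b)`); the pressure
balance therefore holds to machine precision at every accepted sample.
Volume advances by an implicit trapezoidal step solved by fixed-point
iteration (contraction factor ≈ `500·dt/(C·(k1+R_aw))` ≪ 1; iterated to
1e-12 relative). The step is `dt = 4 ms` (250 Hz); halving it changes
steady iPEEP and tidal volume by ≪ 1% even for the narrowest lumen, and a
guard rejects any `dt` coarser than 50 steps per breath phase.

Each run starts from elastic equilibrium at PEEP with zero flow, first
breath inspiratory, and repeats breaths until the end-expiratory tracheal
pressure changes by < 0.01 mbar between consecutive breaths (hard cap 100
breaths, non-converged flag otherwise). iPEEP is reported primarily as the
end-expiratory *tracheal* pressure — the quantity a catheter measures and a
close proxy for alveolar pressure when end-expiratory flow is small — with
the alveolar value alongside. Tidal volume is the trapezoidal integral of
positive flow over the inspiration phase.

The flow-phase discontinuities at breath transitions are smeared over a
single step by the trapezoid; this is the same first-order behaviour as a
250 Hz discrete-update bench controller and is covered by the
dt-convergence check.

## Fitting

The Rohrer fit is linear least squares in `(k1, k2_insp, k2_exp)` with the
basis `(V̇, [V̇≥0]·V̇², −[V̇<0]·V̇²)` — closed-form and deterministic;
negative estimates are clipped to zero with a warning rather than solved
under constraints, since with physically plausible data the unconstrained
optimum is already feasible. Standard errors come from the usual OLS
covariance. One-sided sweeps require the shared-`k2` variant (the design is
otherwise rank-deficient). The power law is fitted by OLS of `log R` on
`log(D_eff/D₀)`, matching its straight-line appearance in log–log
coordinates and avoiding any iterative-solver tolerance; samples are
unweighted. Model error against tabulated resistances is summarised as the
mean absolute percentage error of the secant resistance at 1 L/s.

## Synthetic bench data

`generate_sweep` emulates a slow blower ramp: driving pressure traverses
0 → +80 → 0 → −80 → 0 mbar uniformly in pressure (mirroring a motor-speed
ramp), true flow comes from inverting the Rohrer relation, and additive
zero-mean Gaussian noise is applied to the pressure and flow channels.
`generate_resistance_table` perturbs scaling-law resistances with
multiplicative log-normal scatter. Both are pure functions of their spec
including the seed. What they do **not** emulate: sensor dynamics and
aliasing, low-pass filtering, drift, turbulence-induced heteroscedastic
noise, or real tube-to-tube manufacturing variation — so passing recovery
tests demonstrates estimator correctness within the model class, not
robustness to every artefact of real recordings.

## Problem sizes

The test suite and the acceptance script run full breath-by-breath
simulations at the 4 ms step: a single run is ~1000 samples per breath and
reaches steady state within 2–60 breaths depending on lumen and mode;
diameter sweeps use 5–7 grid points. The whole suite completes in well
under a minute on one CPU.

## Known limitations

* Passive patient only: no spontaneous effort, triggering, or
  patient–ventilator asynchrony (`P_mus` exists but is held at 0).
* One linear compartment: no multi-compartment heterogeneity, nonlinear
  compliance, airway closure/recruitment, or secretions.
* The scaling law is validated for tube diameters 6.0–9.0 mm and scope
  shafts 3.8–5.9 mm; extrapolation far outside (e.g. D_eff ≈ 1 mm) is
  mathematically defined but physically unsupported.
* The ATC controller is ideal apart from the pressure clamp; a real
  blower/valve loop adds lag and tracking error.
* No account of gas compressibility, humidification, or circuit compliance.
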