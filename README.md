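# vwisim

Simulation and quantification toolkit for 3D multi-contrast **black-blood
vessel wall MRI** of the joint intra- and extracranial circulation at 3 T.

Atherosclerosis develops from the common carotid artery up into the middle
cerebral artery, and imaging the *vessel wall* (not just the lumen) across
that whole span requires suppressing the blood signal while preserving wall
signal over a 25 cm field of view with very different flow regimes. This
package models the physics of the three complementary black-blood contrasts
used for that purpose — an iMSDE-prepared spoiled gradient echo (3D-MERGE,
T1-weighted), a reduced-flip-angle 3D turbo spin echo (T2-weighted VISTA),
and a phase-sensitive inversion-recovery SPGR (SNAP, heavy T1 weighting) —
and everything needed to study them end to end on a synthetic digital
phantom: echo-train optimization, flow-suppression design, a labeled
neurovascular phantom with realistic coil gain and Rician noise, curved
cross-section reformatting with ROI-based SNR/CNR measurement, and exact
Wilcoxon signed-rank statistics. It is written for MR physicists and
methods researchers who want a tested, scriptable reference implementation
of these sequence models and of the quantification conventions used in
vessel wall imaging studies.

## The models at the core

* **Extended phase graphs (EPG).** A refocusing train is evolved through
  configuration states (F₊ₖ, F₋ₖ, Zₖ); echo amplitudes of arbitrary flip
  schedules come out of the standard rotation/relaxation/shift operators.
  An independent isochromat Bloch simulator (4000 spins) serves as the
  validation oracle; the two agree to better than 10⁻³ relative error.
* **SNR efficiency of a TSE train.** Each (flip α, echo train length N)
  cell is scored by S_center(α, N) · (N·esp / TR): center-echo intensity
  times acquisition duty cycle. For wall relaxation (T1/T2 = 1114/55 ms,
  TR 2500 ms) the optimal flip falls inversely with train length; at the
  protocol's N = 130 the ridge sits at ≈ 30°, bracketing the constant 32°
  used in practice.
* **Flow-sensitized dephasing.** Moving spins accrue phase γ·M1·v from a
  first gradient moment M1; a uniform intravoxel velocity spread Δφ leaves
  the attenuation factor |sin(Δφ/2)/(Δφ/2)|. The iMSDE preparation adds
  exp(−T_prep/T2), with T_prep the minimal bipolar-encoding duration at the
  20 mT/m gradient cap — larger M1 suppresses slow spins (CSF) better but
  costs wall signal, which is why M1 = 1000 mT·ms²/m is the operating point.
* **Phase-sensitive IR.** The SNAP cycle (inversion → TI → low-flip SPGR
  readout → recovery, period IRTR) is solved in closed form as an affine
  fixed point. At the operating TI the wall is positive, inverted blood
  negative; Re[IR·conj(ref)/|ref|] restores that polarity, so wall-lumen
  contrast is CNR = SNR_w **+** SNR_l for SNAP versus SNR_w − SNR_l for the
  magnitude sequences, with SNR_w = S_w/σ_n and σ_n measured in adjacent
  muscle (neck) or white matter (head) because the noise level varies
  spatially.

## Worked example

```bash
python examples/echo_train_optimization.py
```

```
SNR-efficiency optimization (TR 2500 ms, esp 3.6 ms, wall T1/T2 1114/55 ms)
  grid argmax: flip 23 deg at ETL 200
  ridge flip at ETL  50:  53.6 deg
  ridge flip at ETL  90:  37.0 deg
  ridge flip at ETL 130:  29.5 deg
  ridge flip at ETL 170:  24.8 deg
-> longer trains demand lower flips; at the protocol ETL of 130 the
   optimum (29.5 deg) sits near the protocol's constant 32 deg choice.

Center-echo amplitude of the 32-deg train: 0.0923 of M0
  pure T2 decay at the 255 ms effective TE would give 0.0097;
  the equivalent spin-echo TE is 131 ms
```

The first block is the flip/train-length tradeoff: longer trains acquire
more of each repetition but read the k-space center deeper into the decay,
so the efficiency-optimal refocusing flip drops from ~54° at 50 echoes to
~25° at 170. The second block quantifies why a 255 ms effective echo time is
usable at all: the 32° pseudo-steady train keeps the center echo ~10× above
pure T2 decay, equivalent to a conventional spin echo at ~131 ms.

Other capabilities, one script each, in `examples/`:
`flow_suppression_tradeoff.py` (iMSDE M1 design), `snap_polarity.py`
(signed IR contrast and inflow states), `phantom_quantification.py`
(phantom → three acquisitions → per-location SNR tables), and
`cohort_statistics.py` (multi-subject cohort with Wilcoxon tests). The same
pipeline is scriptable from a shell via the `vwisim` CLI
(`vwisim run-all --subjects 25 --seed 0 --out report/`).

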