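# pmfbind

Umbrella-sampling free-energy analysis for state-dependent drug block of
ion channels: WHAM reconstruction of 1-D potentials of mean force,
PMF-to-dissociation-constant conversion under a cylindrical restraint,
drug-ionization arithmetic, and the patch-clamp curve fits (Hill,
single-exponential, Boltzmann) that accompany such studies — plus a
synthetic-data generator that makes the whole chain testable end to end
without any MD engine or recordings.

The motivating problem is hERG (Kv11.1) channel block: high-affinity
blockers such as dofetilide bind the open and open-inactivated states with
very different affinities, and because the drug's basic amine titrates near
physiological pH, intracellular acidification shifts the neutral/cationic
balance and with it the effective block. Quantifying this requires turning
per-window biased trajectories into a potential of mean force w(z) along
the pore axis and then into a state- and charge-specific binding free
energy.

## The model

Windowed sampling with harmonic biases U_i(z) = (k/2)(z−z₀ᵢ)² is combined
by the weighted histogram analysis method, iterating to self-consistency

    ρ(z_b) ∝ Σᵢ nᵢ(z_b) / Σᵢ Nᵢ exp[(fᵢ − U_i(z_b))/k_BT]
    fᵢ = −k_BT ln Σ_b ρ(z_b) exp(−U_i(z_b)/k_BT)

(tolerance 10⁻⁷ kcal/mol on the fᵢ, Anderson-accelerated). With
w(z) = −k_BT ln ρ(z) offset to zero in bulk and a flat-bottom cylindrical
restraint of radius R, the effective dissociation constant and binding
free energy are

    K_D = [ πR² N_A ∫_site e^(−w(z)/k_BT) dz ]⁻¹ ,   ΔG = k_BT ln(K_D/c⁰) .

Per-bin PMF uncertainties come from a seeded histogram bootstrap over
autocorrelation-corrected effective sample sizes. Protonation follows
Henderson–Hasselbalch, f = 1/(1 + 10^(pH−pKa)). Details, defaults and
caveats: [docs/methods.md](docs/methods.md).

## Worked example

```python
import pmfbind as pb
from pmfbind.io import RunConfig
from pmfbind.pipeline import run_pipeline

# 85 windows every 0.5 A from -49.5 to -7.5 A, k = 10 kcal/mol/A^2,
# 2.2e5 biased samples per window at 310.15 K, two-well ground truth
result, pmf = run_pipeline(RunConfig(seed=1), label="open-like demo")
print(result.summary())
```

prints

```
Binding result open-like demo
  K_D         : 9.4566e-06 M (9.46 uM)
  dG          : -7.13 kcal/mol
  site bounds : [-19.25, -6.95] A
  T           : 310.15 K, R = 10 A, c0 = 1 M
  note        : effective 1-D estimate under a cylindrical restraint
```

The reconstructed PMF tracks the analytic two-well truth to an RMS of
0.042 kcal/mol at these sampling sizes, and the K_D above is within 1% of
the preset's closed-form value over the same site — the kind of agreement
to expect when the only error source is sampling noise. Converting
measured dissociation constants is direct:

```python
>>> pb.dg_from_kd(1.32e-9)        # 1.32 nM at 310.15 K, in kcal/mol
-12.601285299693297
>>> 100 * pb.protonated_fraction(ph=7.4, pka=7.0)
28.474724895080122
```

The same stages run from the shell, each stage re-runnable from the
previous one's files:

```sh
pmfbind pipeline --seed 1 --out demo/          # simulate -> wham -> bind
pmfbind wham demo/metadata.txt --out demo/pmf.tsv
pmfbind bind demo/pmf.tsv --out demo/binding.tsv
pmfbind fit blocks.tsv --model hill
```

Trajectory files are one z sample per line; the metadata file is the
whitespace dialect of common 1-D WHAM tools (`path centre force-constant`,
`#` comments).

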