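# oligosas

Oligomeric-state deconvolution of small-angle scattering data from
flexible multi-domain proteins.

Many proteins — the *E. coli* replication initiator DnaA is the
motivating case — populate a mixture of association states (monomer,
dimer, …) in solution, and carry flexible linkers that make any single
rigid model a poor description of the scattering. A 1-D SAXS/SANS curve
I(Q) of such a sample is a population-weighted average over both
oligomeric states and conformers. `oligosas` disentangles it: it builds
coarse-grained conformer pools for each oligomer state (monomer through
pentamer) with a mobile domain on a flexible linker, computes
per-particle Debye curves, and selects — with a genetic algorithm in the
ensemble-optimization-method (EOM) tradition — the sub-ensemble whose
average best fits the data. The per-state selection frequencies are the
inferred oligomer fractions, with run-to-run SD from repeated GA runs.

The package also provides the standard primary analytics and a synthetic
data generator, so the whole chain is verifiable without experimental
curves:

- **Guinier fit**: ln I = ln I(0) − Q²Rg²/3 over an automatically chosen
  low-Q window (Q·Rg ≤ 1.3).
- **P(r)**: regularized indirect Fourier transform
  I(Q) = 4π ∫₀^Dmax P(r) sinc(Qr) dr with P(0) = P(Dmax) = 0, P ≥ 0,
  smoothness regularization, and Dmax optimization by a composite
  quality score.
- **Debye scattering**: I(Q) = Σᵢⱼ fᵢfⱼ sin(Qrᵢⱼ)/(Qrᵢⱼ), exact or via a
  pair-distance histogram.
- **χ² fitting**: reduced χ² with the analytic least-squares scale.
- **Synthetic mixtures**: known ground-truth fractions (presets anchored
  to the reported DnaA nucleotide states) with σ(Q) = a·I + b noise.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Simulate an apo-like mixture (69.4% monomer / 28.4% dimer / 2.2% trimer,
2% relative noise) from a desk-scale pool and recover the composition:

```python
import oligosas as og

arch = og.DomainArchitecture()           # head 1-108, linker 109-129, core 130-467
q = og.default_q_grid()                  # 150 points, 0.008-0.35 1/A
pool = og.generate_pool(arch, orders=[1, 2, 3, 4, 5], n_per_state=200,
                        q_grid=q, seed=7)

truth = og.preset("apo-like", seed=3)
data, provenance = og.make_mixture_profile(pool, truth)

guinier = og.guinier_fit(data)
print(f"Guinier: Rg = {guinier.rg:.1f} A, I(0) = {guinier.i0:.0f}")

report = og.fit_report(data, pool, og.GAConfig(seed=0, n_runs=3))
best = min(float(v) for v in report["best_single_chi2"].values())
print(f"best single-conformer chi2 = {best:.2f}")
print(f"ensemble chi2 per run      = "
      + ", ".join(f"{c:.2f}" for c in report["ensemble_chi2_per_run"]))
dist = report["distribution"]
for state, name in [("1", "monomer"), ("2", "dimer"), ("3", "trimer")]:
    print(f"{name:8s} {100*dist['fraction'][state]:5.1f} % "
          f"(SD {100*dist['sd'][state]:.1f})")
```

Output:

```
Guinier: Rg = 34.3 A, I(0) = 439440
best single-conformer chi2 = 21.73
ensemble chi2 per run      = 1.00, 0.99, 0.99
monomer   66.7 % (SD 1.9)
dimer     32.0 % (SD 2.8)
trimer     1.3 % (SD 0.9)
```

The Guinier Rg (34.3 Å) exceeds any single monomer conformer — the
first hint of a mixture. No single conformer of any state fits the
curve (best χ² = 21.7), while the GA-selected 50-member ensemble fits
to within the noise (χ² ≈ 1.0), and its per-state selection frequencies
recover the generating fractions to within ~3 percentage points, with
the SD over three independent GA runs shown in brackets.

The same workflow is available from the shell:

```sh
oligosas buildpool --orders 1,2,3,4,5 --n 200 --seed 7 --out pool/
oligosas simulate --preset apo-like --pool pool/ --seed 3 --out apo.dat
oligosas guinier apo.dat
oligosas pr apo.dat --dmax-scan 60:140:10
oligosas fit apo.dat --pool pool/ --seed 0 --out report/
oligosas pipeline simulate --out run/        # the full chain, one command
```

All outputs are JSON/CSV; every run echoes its configuration and seeds
and is bit-reproducible from them.

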