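# tfchannel

How much can a single promoter "know" about the strength of a stimulus
when that strength is encoded in the **duration**, **amplitude** or
**pulse frequency** of a transcription factor's nuclear concentration?
`tfchannel` answers this with a stochastic transcription simulator and
an information-theoretic readout: it treats the promoter as a noisy
channel from the encoded input to the accumulated mRNA output and
measures the mutual information the channel transmits.

The package is aimed at systems-biology modelers studying pulsatile TF
dynamics (Msn2-like multi-stress regulators, p53, NF-κB): it provides
the simulation, estimation and parameter-search machinery to ask which
promoter kinetics maximize information transmission for each encoding,
and whether promoters can be tuned to read one encoding while staying
blind to another.

## Model

A promoter switches between inactive and active states under cooperative
TF control, and transcription is a birth-death process driven by the
active state:

    dP1/dt = k1·h(TF) − (k1·h(TF) + d1)·P1,        h(TF) = TF^n / (TF^n + Kd^n)

    X → X+1  at rate  k2·h(TF(t))·P1(t)            (transcription)
    X → X−1  at rate  d2·X                          (mRNA degradation)

The output is the integrated copy number `Out(T) = ∫₀ᵀ X dt` at
mode-specific cuts Ta/Tb/Tc.  Inputs are square TF pulses on a 100-min
window with rectified Gaussian amplitude noise (SD 10 a.u.); the input
value is drawn uniformly from a 200-point grid (pulse length 1–10 min,
pulse height 0–100 a.u., or Poisson pulse rate (0, 0.1]/min).  Mutual
information

    MI(I; O) = H(I) + H(O) − H(I, O)     [bits]

is estimated from the joint histogram of input values and
quantile-binned outputs, with a jackknife (subsample extrapolation in
1/N) correction for undersampling bias.  On top of single-channel
estimates the package provides MI-versus-time curves with an exponential
tail fit, 1-D/2-D parameter sweeps, log-scale Latin-hypercube searches
over promoter kinetics, and the *Minmax* analysis that looks for
promoters maximizing MI for one encoding while minimizing it for
another.

## Worked example

Mutual information between pulse amplitude and accumulated mRNA for a
fast, high-threshold promoter, at a reduced scale (100 input values,
400 replicates each; about a minute of compute):

```python
import tfchannel as tc

promoter = tc.KineticParams(k1=1.0, k2=100.0, n=10.0, Kd=70.0, d1=0.01)
config = tc.SimConfig(n_reps=400, seed=11)

est = tc.mi_pipeline(promoter, "amplitude", "Tc", config,
                     n_inputs=100, n_bins=32)
print(f"MI = {est.mi_bits:.3f} bits (plug-in {est.mi_plugin_bits:.3f}, "
      f"n = {est.n_samples})")
```

```
MI = 1.194 bits (plug-in 1.211 bits, n = 40000)
```

About 1.2 bits means the promoter resolves roughly `2^1.2 ≈ 2.3`
amplitude ranges: amplitudes below the effective activation threshold
(≈ 50 a.u. for Kd = 70, n = 10) all produce essentially no mRNA, and the
amplitude noise blurs the remainder into two to three distinguishable
levels.  The jackknife estimate sits slightly below the plug-in value
because the correction removes the finite-sample inflation of the raw
histogram estimate.

The same promoter is nearly blind to a threshold-free channel: with
`Kd=10, n=1` (promoter saturated by noise alone) the pipeline returns
MI ≈ 0.01 bits — every input produces statistically indistinguishable
output.

The CLI exposes each stage (`tfchannel --help`): `simulate`, `mi`,
`mi-time`, `decay-fit`, `sweep1d`, `sweep2d`, `lhs`, `mi-table`,
`minmax`, `report`.  For example,

```bash
tfchannel lhs --n-sets 100 --seed 1 -o design.csv
tfchannel mi-table --design design.csv --profile desk -o table.csv
tfchannel minmax --table table.csv -i duration -j frequency -o region_02.json
```

draws a 100-set log-scale Latin hypercube over the study ranges
(k1 ∈ (0.01,1), k2 ∈ (1,100), n ∈ (1,10), Kd ∈ (10,100), d1 ∈ (0.01,1)
with d2 = 0.12/min fixed), evaluates MI for all 9 modulation × cut
combinations per set (resumable — rerunning skips finished sets), and
extracts the promoters that transmit duration well while staying blind
to frequency.

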