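# coopbind

Analytics for **cooperative protein–DNA recognition** from molecular
ensembles.  The package is written for structural biologists studying how a
partner transcription factor changes the DNA-binding of a multi-domain
factor — the motivating system being OCT4 (POU-specific domain POU_S +
POU homeodomain POU_HD) co-binding a composite motif with SOX2, where
cooperativity arises from an interplay of a direct protein–protein interface
and DNA-mediated allostery.

## What it computes

**Free-energy core.**  Umbrella-sampling windows along the minimal
protein–DNA heavy-atom distance d_min are unbiased with WHAM into a profile
G(d_min); the macroscopic binding free energy is

ΔG = −k_B·T · ln [ ∫_bound ρ(d_min) d d_min ∕ ∫_unbound ρ(d_min) d d_min ],
ρ ∝ exp(−G/k_B T),

swept over bound/unbound thresholds (3.1–4.3 Å).  With ΔG for each domain
measured with (+) and without (−) the partner, the cooperativity is the sum
of partner-induced per-domain changes,

ΔΔG_coop = [ΔG_S(+) − ΔG_S(−)] + [ΔG_HD(+) − ΔG_HD(−)],

with quadrature errors.  Per-bin profile errors come from a Bayesian
bootstrap over decorrelated samples; a θ diagnostic scores the sampling
consistency of consecutive windows.

**Ensemble analytics.**  Contact maps (≤ 4.5 Å, recurrent = present in
> 50% of frames) with per-residue and unbinding-survival profiles;
docking-helix *Rock*/*Tumble* orientation angles in a DNA-anchored frame
with conformational-area ratios; simplified DNA groove widths and axis
bending with block-averaged errors; dynamic networks (persistence-filtered
contact edges weighted −log|C_mn|) with shortest/suboptimal communication
paths and Girvan–Newman communities.

**Synthetic data.**  Seeded generators provide an ideal B-form duplex, toy
protein–DNA ensembles with controlled contact persistence and correlated
motion, Brownian umbrella sampling on prescribed 1D landscapes, and
scheduled-unbinding ensembles — so the entire pipeline is testable without
any trajectory downloads.  See `docs/methods.md` for the models,
conventions and their limits.

## Worked example

The packaged per-domain affinity table (kcal/mol, per bound/unbound
threshold) is reduced to cooperativities and domain deltas:

```sh
coopbind coop --out out/
```

```
 threshold  ddG_coop  ddG_coop_err  delta_s  delta_s_err  delta_hd  delta_hd_err  hd_minus_s_apo ...
       3.1      0.96          0.20     0.65         0.11      0.31          0.16            1.11
       3.3     -2.00          0.15    -2.38         0.09      0.38          0.12           -1.80
       3.5     -2.59          0.16    -2.74         0.09      0.15          0.13           -2.23
       3.7     -3.49          0.16    -3.02         0.08     -0.47          0.14           -2.44
       3.9     -4.51          0.12    -3.14         0.08     -1.37          0.09           -2.45
```

Reading the 3.3–3.5 Å rows (where the bound→unbound transition is sharpest):
the partner stabilizes POU_S on the DNA by 2.4–2.7 kcal/mol (`delta_s`)
while slightly destabilizing POU_HD (`delta_hd` +0.15 to +0.38), for a net
cooperativity of −2.0 to −2.6 kcal/mol; without the partner the homeodomain
binds 1.8 kcal/mol stronger than POU_S (`hd_minus_s_apo` −1.80).
`coopbind audit` additionally recomputes the cooperativity column and flags
the 4.1/4.3 Å rows of the packaged table as internally inconsistent
(a likely typo in one ΔG column — reported, never corrected).

A fully synthetic free-energy pipeline, end to end:

```sh
coopbind simulate-umbrella --out win/ --seed 1        # Brownian sampling
coopbind wham --windows win/ --out prof/ --n-boot 40  # G(d_min) + errors + θ
coopbind dg --profile prof/profile.tsv --out dg/ --thresholds 3.6 --upper 5.25
```

On the packaged double-well landscape this recovers the profile to
≈ 0.07 kcal/mol RMS and the closed-form ΔG (−1.69 kcal/mol at the 3.6 Å
barrier) to within 0.04 kcal/mol, with max θ ≈ 0.07 across window pairs.

Every stage writes its resolved configuration (`config.json`) next to its
outputs, and identical seeds reproduce all numbers bit-for-bit.

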