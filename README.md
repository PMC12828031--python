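# cascadeflim

Three-colour FRET-cascade analysis for TCSPC-FLIM: from fluorescence-decay
histograms to energy-transfer rates, fluorophore geometry and molecular
tension maps.

## Who this is for

Cell biophysicists using fluorescence lifetime imaging (FLIM) with
time-correlated single photon counting (TCSPC) to study multi-fluorophore
FRET systems — in particular three-colour cascades, where the first acceptor
also donates to a second acceptor — and molecular tension sensors such as
the vinculin TSMod construct. The package covers the complete analysis
chain and ships a synthetic-data generator so every stage can be validated
against known ground truth without any raw microscope data.

## The model

A donor with intrinsic lifetime τ_D acquires an extra de-excitation pathway
per FRET acceptor. For the measured lifetime τ_DA:

    1/τ_DA = Γ_DA + 1/τ_D                     (transfer rate Γ)
    E      = Γ / (Γ + 1/τ_D) = 1 − τ_DA/τ_D   (pairwise efficiency)

With n acceptors the transfer rates add:

    E_D = Σ_j Γ_Dj / (Σ_j Γ_Dj + 1/τ_D)

and each rate encodes a separation through the Förster law:

    Γ = (1/τ_D) (R₀ / r)⁶     ⇔     r = R₀ ((1−E)/E)^{1/6}

Three pairwise separations fix the planar triangle formed by the three
fluorophores. For a tension sensor, the separations of the loaded (TS) and
zero-force tailless (TL) constructs give the mean force across the elastic
linker of N amino acids:

    ⟨F⟩ = (⟨R_TS⟩ − ⟨R_TL⟩) · (0.01196 N + 0.0001255)

Pixel-wise force histograms are modelled as a two-Gaussian mixture
(low/high tension populations).

## Worked example

Rate decomposition of a three-colour cascade from its control-construct
lifetimes (`examples/01_cascade_rates.py`):

```
intrinsic donor rate       2.39e+08 s^-1
transfer to intermediate   1.35e+08 s^-1
direct transfer to far FP  6.91e+07 s^-1
predicted cascade lifetime 2.253 ns (measured 2.331 ns)
calculated vs measured total rate differ by 3.36%
```

The donor-alone lifetime (4.178 ns) sets the intrinsic rate; the pairwise
and dark-intermediate constructs yield the two transfer rates; summing them
predicts the full three-colour lifetime. The 3.36% residual between the
calculated and measured total rates says the two FRET pathways behave as
independently additive de-excitation channels.

A full synthetic tension round trip (`examples/03_tension_round_trip.py`)
simulates TS and TL FLIM scenes at 10⁵ photons/pixel, fits every pixel, and
recovers the ground-truth adhesion force:

```
no-tension reference separation 4.200 nm (generator used 4.2 nm)
recovered adhesion force 3.01 pN (truth 3.00 pN)
```

The other examples cover decay simulation and fitting, bimodal population
fits, and triangle geometry; each prints its results with a line on what
they mean.

A thin CLI wraps the same functions
(`cascadeflim simulate|fit|cascade|geometry|force|run-construct|run-tension`,
see `cascadeflim --help`); the YAML config schema is documented in
`cascadeflim/config.py`.

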