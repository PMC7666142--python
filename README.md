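# seacosm

Growth and mortality rates of marine bacterioplankton groups from seawater
microcosm manipulation experiments.

## The problem

How fast do different bacterioplankton groups grow in the sea, and what keeps
them in check — protistan grazing, viral lysis, or competition for resources?
A classical way to ask this is a manipulation experiment: the same seawater is
incubated under treatments that selectively remove pressures, and
group-specific cell densities (e.g. CARD-FISH counts) are followed over one to
two days:

| code | manipulation | pressures retained |
|------|--------------|--------------------|
| CT   | whole seawater | all |
| PR   | 1-µm filtrate (predator-reduced) | resources, viruses |
| DI   | 1:4 dilution with 0.2-µm filtrate | grazing ×D, resources ×D, viruses |
| VR   | 1:4 dilution with 30-kDa filtrate (virus-reduced) | all ×D |

with dilution factor D = 0.25; CT and PR are additionally run in continuous
dark (`_D`) next to the light/dark-cycle bottles (`_L`).

`seacosm` implements the computational side of such a campaign: net growth
rates from ln-linear regression of abundance vs time, the four-equation
budget that partitions them into gross growth and loss terms, treatment
response ratios, comparative statistics, and a fully synthetic experiment
generator with known ground truth (no field data are required to exercise
the pipeline).

## The model

For each group, the net growth rate `k` (day⁻¹) in each treatment is a linear
budget on the gross growth rate µ and per-capita losses — grazing mortality
m_g, a resource-limitation constraint r_c, viral mortality m_v:

```
k_CT = µ − (m_g + r_c + m_v)
k_PR = µ − (r_c + m_v)
k_DI = µ − (D·m_g + D·r_c + m_v)
k_VR = µ − D·(m_g + r_c + m_v)
```

For D ≠ 1 the system has the unique closed-form inverse

```
m_g = k_PR − k_CT
m_v = (k_VR − k_DI) / (1 − D)
r_c = (k_DI − k_PR + D·m_g) / (1 − D)
µ   = k_PR + r_c + m_v
```

Response ratios between treatment pairs (PR/CT grazing, DI/PR resources,
VR/DI viruses, L/D light) quantify the release from each pressure; values
above 1 indicate release.

## Worked example

```python
import seacosm as sc

config = sc.PipelineConfig(output_dir="demo_out", seed=42)
bundle = sc.run_pipeline(config)
print(bundle.partitions[bundle.partitions.season == "winter"].round(3))
```

simulates the four-season campaign (six treatments, triplicate bottles,
lognormal counting noise at 10 % CV), fits all rates and prints the winter
mortality partition, e.g.:

```
season group    mu   m_g   r_c    m_v  negative_components
winter   ALT 3.031 1.688 0.969  0.060
winter   CFB 0.818 0.506 0.188 -0.068                  m_v
winter SAR11 0.640 0.252 0.121  0.079
...
```

Read: in this simulated winter, *Alteromonadaceae* (ALT) grows grossly at
about 3 day⁻¹ but loses ~1.7 day⁻¹ to grazers; SAR11 grows slowly
(µ ≈ 0.6 day⁻¹) with losses dominated by grazing. A negative component (CFB's
m_v here) is measurement noise propagated through the algebra — it is flagged,
not hidden. The corresponding response ratios:

```python
r = bundle.ratios
print(r[(r.season == "winter") & (r.group == "SAR11")].round(3))
```

```
  kind      numerator denominator  ratio
  grazing   PR_L      CT_L         2.351
  resources DI_L      PR_L         1.064
  viruses   VR_L      DI_L         1.127
  light     CT_L      CT_D         1.711
```

— removing predators more than doubles SAR11's realized growth, while extra
resources or virus removal change it little.

The same stages are available from the shell:

```bash
seacosm simulate --seed 42 --out abundance.csv
seacosm estimate abundance.csv --out rates.csv
seacosm partition rates.csv --out partitions.csv
seacosm ratios rates.csv --out ratios.csv
seacosm report --seed 42 --out demo_out
```

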