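# wqikit

A water quality index (WQI) engine for drinking-water monitoring
programmes whose datasets have missing values, plus the statistical
tooling used to summarise and validate the index: descriptive statistics,
class-share summaries, correlation-matrix PCA with Kaiser retention, and
OLS of the index on component scores.

## Who this is for

Water-quality analysts who need to collapse a wide table of sample
measurements (concentrations in mg/L, turbidity in NTU, pH) into a single
dimensionless score per sample — and whose monitoring records are
incomplete, because decentralized monitoring sectors measure different
parameter subsets. Classic fixed-weight indices simply discard any record
missing a parameter; this index does not.

## The index

Each criteria parameter *i* has a fixed importance weight *wᵢ* and a
guideline limit *Lᵢ*. For one sample, only the parameters that are
actually available (included, not struck by a per-record selection code,
and measured) enter the computation, and the weights are renormalized over
that set — the *dynamic weights*:

    Wᵢ = wᵢ / Σⱼ∈available wⱼ          (so Σ Wᵢ = 1)

Each available parameter contributes a quality value

    qᵢ = (cᵢ / Lᵢ) · 100 · Wᵢ

except pH, which is banded: q = 0 for 6.5 ≤ pH ≤ 8.5, q = (6.5/pH)·100·W
below the band and q = (pH/8.5)·100·W above it. The WQI is the sum of the
quality values, so a sample sitting exactly at every limit scores 100
regardless of which parameters happened to be measured. Classification:
<50 excellent, 50–100 good, 100–200 poor, 200–300 very poor, ≥300
unsuitable for drinking.

The bundled default criteria set has 13 parameters (pH, calcium,
magnesium, chloride, TDS, fluoride, manganese, nitrate, iron, sulfate,
ammonium, sodium, turbidity) with weights summing to 46; total hardness is
available but excluded by default since it double-counts calcium and
magnesium.

## Worked example

`samples.csv` — note the empty ammonium cell in `well-2` (missing value)
and the `-1` selection code striking ammonium from `well-3`:

```
sample_id,pH,nitrate,tds,turbidity,ammonium,ammonium_code
well-1,7.2,12.5,640,2.0,0.4,
well-2,6.1,48.0,995.5,8.5,,
well-3,8.0,5.0,120,0.5,1.2,-1
```

```
$ wqikit compute --in samples.csv --criteria default --out report.csv
wrote 3 samples to report_original_data.csv, report_quality_values.csv, report_water_quality_index.csv

$ cat report_water_quality_index.csv
sample_id,WQI,interpretation
well-1,31.05,Excellent water quality
well-2,116.73,Poor water quality
well-3,8.12,Excellent water quality
```

Reading `well-2`: only pH, nitrate, TDS and turbidity are usable (weights
4, 5, 4, 4 → dynamic weights 4/17, 5/17, 4/17, 4/17). pH 6.1 is below the
band, so it contributes (6.5/6.1)·100·(4/17) = 25.07; nitrate at 48 of 50
mg/L contributes (48/50)·100·(5/17) = 28.24; together with TDS (23.42) and
turbidity at 8.5 of 5 NTU (40.00) the index is 116.73 — poor water
quality, driven by the turbidity exceedance. The per-parameter terms are
in `report_quality_values.csv`; each row sums to the sample's WQI.

The report has three parts (one workbook with three sheets under
`--format xlsx`, or three CSV files): "Original Data" echoes the input
verbatim, "Quality Values" holds the per-parameter contributions, "Water
Quality Index" the totals and interpretations.

Other subcommands:

```
wqikit simulate --n 735 --seed 1 --out synthetic.csv   # synthetic survey
wqikit stats --in report_water_quality_index.csv        # descriptive block + class shares
wqikit pca --in synthetic.csv                           # complete-case PCA + WQI regression
```

As a library, the same pipeline is
`generate` → `compute_many` → `describe` / `class_shares` →
`filter_complete` → `pca_correlation` → `ols_wqi_on_scores`.

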