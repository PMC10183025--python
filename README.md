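# sdindex

Daily standardized drought indices — **SPI**, **SPEI** and **SSMI** — computed
nonparametrically: per calendar day, the cross-year sample of (aggregated)
values is fitted with a Gaussian kernel density whose bandwidth minimizes the
unbiased least-squares cross-validation criterion, and each value's cumulative
probability is mapped equiprobabilistically to a standard-normal score.
Precipitation uses a zero-inflated mixture (point mass at zero plus a KDE on
the strictly positive values) so dry-day probability is never smeared.

Also included:

- Hargreaves–Samani potential evapotranspiration with extraterrestrial
  radiation derived from latitude and day of year alone (MJ m⁻² day⁻¹).
- Trailing rolling aggregation for 5–720-day timescales (default scheme:
  5…365 step 5, then 370…720 step 10; 109 periods). SSMI is unaggregated.
- McKee / Agnew / U.S. Drought Monitor classification and the cross-site
  drought-area fraction.
- Diagnostics: nRMSE, R², day-of-year z-transform, rolling correlation fields.
- A seeded synthetic-weather generator (zero-inflated seasonal rain, AR(1)
  temperatures, leaky-bucket soil moisture) plus exact-distribution oracles
  for testing.
- CSV I/O matching the published per-site layouts
  (`[site]_input.csv`, `SPI_[site].csv`, `SPEI_[site].csv`, `SSMI_[site].csv`).

## CLI

```sh
# synthetic 72-year site table
sdindex simulate --seed 1 --years 72 --out site_input.csv

# fill RG/PET columns from latitude + temperatures
sdindex compute-pet --input site_input.csv --out site_input.csv

# indices (all aggregation periods, or a comma list)
sdindex compute-indices --input site_input.csv --index spi --agg 30 \
    --site-name demo --outdir out/

# categories and drought-area fraction
sdindex classify --input out/SPI_demo.csv --scheme usdm --fraction --outdir out/

# paired-series statistics
sdindex diagnose --obs a.csv --sim b.csv --obs-column v --sim-column v
```

Every tunable (window completeness threshold, minimum climatology size,
bandwidth method, wet-day threshold, Feb-29 pooling, output precision, …) has
a default in `sdindex.config.Settings` and can be overridden by a YAML file
passed with `--config`.

## Library sketch

```python
import sdindex as sx

cfg = sx.SyntheticSiteConfig(years=72, seed=1)
table = sx.generate_site(cfg)

idx = __import__("pandas").DatetimeIndex(table["Date"])
prec = sx.DailySeries(idx, table["PREC"].to_numpy(float), "mm")
pet = sx.DailySeries(idx, table["PET"].to_numpy(float), "mm")

spei = sx.compute_spei(prec, pet, sx.AggregationScheme((30, 90, 365)))
label = sx.classify(spei.frame["SPEI_30"].iloc[-1], "usdm")
```

## Notes

- The standardization is *in-sample* (each year is scored against a
  climatology that includes it). At 72 years this compresses the pooled score
  SD to ≈0.89 and the frequency of scores < −1.28 to ≈0.078; this is inherent
  to KDE-smoothed probability transforms at this sample size, not a bug.
- Feb 29 is pooled with Feb 28 into one climatological sample.
- Radiation is stored in MJ m⁻² day⁻¹ (multiply by 11.574 for W m⁻²).
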