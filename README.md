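# tagpower

Evaluation toolkit for association-study designs on phased haplotype
panels. It answers four questions about a panel of phased biallelic SNPs:

1. **LD spectrum** — how strong is pairwise r² within 50/100/200 kb
   windows (or within genes), stratified by minor-allele-frequency class
   (common > 5%, low-frequency 0.5–5%, rare ≤ 0.5%)?
2. **Tagging** — how many greedy pairwise tag SNPs are needed at an r²
   threshold, which SNPs land in which bin, and which are untaggable?
3. **Coverage** — what fraction of the panel's variation does a fixed
   array manifest capture, directly or through an r² ≥ threshold proxy?
4. **Power** — what is the Monte-Carlo power of the 2-df chi-square
   case-control test under dominant / additive / multiplicative /
   recessive disease models, testing the causal SNP itself, its best
   panel proxy, or its best proxy on a fixed array?

A synthetic-data module generates chromosome-scale or multi-gene panels
with a neutral folded site-frequency spectrum and block-structured,
distance-decaying LD (founder-copying mosaic), plus discovery-subsample
ascertained array manifests, so the whole pipeline is testable offline.

## Library quick tour

```python
import tagpower as tp

cfg = tp.SimulationConfig(seed=1, n_samples=55, n_variants=2000)
panel = tp.generate_panel(cfg)                       # HaplotypePanel
tp.write_phased_vcf(panel, "panel.vcf")

profiles = tp.pairwise_ld_profile(panel, window=200_000)
assignment = tp.greedy_select_tags(panel, threshold=0.8)

manifest = tp.ascertain_discovery_panel(panel, panel.sample_ids[:20])
report = tp.coverage_at_threshold(panel, manifest, threshold=0.8)

model = tp.DiseaseModel.from_rr_hom("dominant", rr_hom=1.8, prevalence=0.01)
est = tp.estimate_power(panel, panel.variants[0].id, model,
                        n_cases=5000, n_controls=5000, replicates=1000)
```

## CLI

Every stage is a subcommand; `run` drives them all from one YAML config.

```bash
tagpower simulate --seed 1 --n-samples 55 --n-variants 2000 \
    --discovery-samples 20 --out-prefix panel
tagpower ld --vcf panel.vcf --window 100000
tagpower tag --vcf panel.vcf --r2-threshold 0.8 --window 200000
tagpower coverage --vcf panel.vcf --manifest panel.manifest.tsv
tagpower power --vcf panel.vcf --model additive --rr-hom 1.8 \
    --n-cases 5000 --n-controls 5000 --replicates 1000
tagpower validate --config run.yaml
tagpower run --config run.yaml
```

Example `run.yaml`:

```yaml
seed: 7
outdir: out
stages:
  simulate: {n_samples: 55, n_variants: 2000, region_length: 1000000,
             discovery_samples: 20}
  ld:       {window: 100000}
  tag:      {r2_threshold: 0.8, window: 200000}
  coverage: {thresholds: [0.2, 0.5, 0.8]}
  power:    {model: additive, rr_hom: 1.8, n_cases: 1000, n_controls: 1000,
             replicates: 200, max_causal: 50}
```

All outputs are TSV with commented headers; reruns with the same config
and seed are byte-identical, and `run_manifest.json` records the config
hash and output list.

## Formats

* **VCF** (uncompressed, phased `GT`, biallelic SNPs only) — unphased,
  missing or multiallelic records are hard errors; monomorphic records
  are dropped with a logged count.
* **IMPUTE-style `.hap`/`.legend`** pairs as a secondary dialect.
* **BED** (0-based half-open) for gene regions.
* **Array manifests** as two-column TSV (`chrom`, `pos`, 1-based).

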