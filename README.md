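# ibdscan

Genome-wide significance thresholds for selection scans on
identity-by-descent (IBD) segment rates, with family-wise error rate
(FWER) control.

## The problem

Recent positive selection leaves an excess of long IBD haplotype
segments around the selected locus.  Scanning the genome for positions
where the IBD rate — the fraction of haplotype pairs sharing a
detectable segment overlapping that position — is unusually high is an
established way to find such loci, but the rates at nearby positions are
strongly correlated, so neither a fixed "four standard deviations above
the median" heuristic nor a Bonferroni correction over tens of thousands
of grid positions gives calibrated genome-wide significance.

`ibdscan` models the standardized IBD rates Z̃_m along the genome as an
Ornstein–Uhlenbeck (OU) process with autocorrelation exp(−θ·d) at
genetic distance d Morgans, estimates θ from the data, and converts a
family-wise level α into a per-position quantile z* by either

* root-solving the boundary-crossing approximation

  P(max_m Z̃_m ≥ z) ≈ 1 − exp(−[ C(1−Φ(z)) + θ L z φ(z) ν(z√(2θΔ)) ]),

  where L is the genome length in Morgans, C the chromosome count, Δ the
  test spacing and ν Siegmund's discretization correction; or

* Monte Carlo simulation of the discretely sampled OU chain, taking the
  empirical (1−α) quantile of genome maxima.

The scan rejects where Z̃_m > z*, reports contiguous significant
stretches of at least 0.5 cM with peak positions and p values, and ships
an OU-based validation harness that measures empirical FWER on simulated
null genomes.

It is intended for population-genetics practitioners who already have
detected IBD segments (hap-ibd / ibd-ends style `.seg` files) and a
recombination map, and want calibrated genome-wide thresholds instead of
ad-hoc cutoffs.

## Worked example

The snippet builds a synthetic ten-chromosome dataset of 200 diploid
samples with a selection-like pile-up of extra segments at 50 cM on
chromosome 2, then runs the full scan:

```python
import numpy as np
from ibdscan import IBDScan, SampleInfo, uniform_map, synthetic_segment_file

rng = np.random.default_rng(42)
gmap = uniform_map([100.0] * 10)          # ten 100 cM chromosomes, 1 Mb/cM
synthetic_segment_file(
    "example.seg", n_samples=200, ploidy="diploid",
    chrom_lengths_cm=[100.0] * 10, gmap=gmap,
    mean_rate=1e-3, length_scale_cm=3.0, rng=rng,
)
with open("example.seg", "a") as fh:      # inject the selected locus
    for i in range(400):
        fh.write(f"x{i}\t1\ty{i}\t2\t2\t48500000\t51500000\t3.0\n")

model = IBDScan.from_files("example.seg", gmap, SampleInfo(200),
                           min_cm=2.0, delta_cm=0.1)
res = model.fit(seed=1)
print(res.summary())
```

Output:

```
IBD rate selection scan
============================================================
Grid: M=9610 tests on C=10 chromosomes, Delta=0.1 cM, L=10.000 Morgans
Robust moments: mean=0.0009979  SD=0.000112  outliers excluded=31
OU decay: theta_hat=65.98 per Morgan (40 lags)

Thresholds at family-wise alpha=0.05:
  analytical  z*=4.2627  alpha*=1.010e-05 *
  simulation  z*=4.3391  alpha*=7.155e-06
  bonferroni  z*=4.4086  alpha*=5.203e-06
  heuristic   z*=4.0000  alpha*=3.167e-05

Significant regions (>= 0.5 cM contiguous, analytical threshold): 1
  chr2  rate=5.945e-03  size=3.00 cM  peak=51.50 Mb  p=underflow
```

Reading it: the scan grid has 9610 tests (ten chromosomes, 0.1 cM steps,
2 cM trimmed from each end to match the 2.0 cM segment detection
threshold).  The background IBD rate is ≈ 1e−3 with SD ≈ 1.1e−4; the 31
excluded outliers are the injected peak, kept out of the moments by the
two-pass rule.  The fitted OU decay θ̂ ≈ 66 per Morgan sets the
analytical threshold at z* = 4.26 — more stringent than the legacy
heuristic (z = 4) but an order of magnitude less stringent than
Bonferroni on the α* scale.  Exactly one region is called: the injected
3 cM stretch on chromosome 2, peak rate 5.9e−3 at 51.5 Mb, with a normal
p value too small to represent in double precision (`underflow`).

The same scan is available from the shell:

```bash
ibdscan scan --segments example.seg --map example.map --samples 200 \
    --min-cm 2.0 --step-cm 0.1 --out-prefix example
ibdscan thresholds --theta 50 --length-cm 1000 --chromosomes 10
ibdscan validate-fwer --theta 50 --reps 500 --out fwer.json
```

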