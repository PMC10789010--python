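# nuptscan

Detection and spatio-temporal characterization of **NUPTs** — nuclear
plastid DNA sequences, the stretches of a plant nuclear genome that were
copied from the chloroplast genome and can still be aligned back to it.

Plant nuclear genomes carry anywhere from ~0.1% to several percent of
plastid-derived DNA. Mapping that fraction, dating the transfer events,
and describing how integrants are arranged (clusters, hotspots, donor
bias, flanking base composition) is the core of NUPT studies. `nuptscan`
implements that analysis end to end for people who want a reproducible,
testable pipeline rather than a chain of one-off scripts:

- **Detection** — seed-and-extend local alignment of the plastid against
  the nuclear assembly (word size 9, +1/−2 scoring, affine 5+2g gaps,
  Karlin–Altschul e-values, e ≤ 1e−5), or ingestion of standard 12-column
  BLAST tabular output; DUST-style masking of low-complexity query
  regions that otherwise produce spurious alignments; each surviving HSP
  is one NUPT.
- **Inverted-repeat correction** — plastid genomes are quadripartite
  (LSC–IRA–SSC–IRB); a donor inside the IR yields one hit per IR copy at
  the same nuclear locus. `nuptscan` finds the IR pair, projects IRB
  donors onto IRA (mirror transform) and counts each integrant once;
  genome fractions are reported raw and deduplicated.
- **Episodic-age model** — percent identity is a relative-age proxy
  (molecular clock): the identity distribution is fitted as a univariate
  Gaussian mixture by EM, the number of components k is chosen by a
  parametric-bootstrap likelihood-ratio test (k vs k+1, p = (1 + #{boot ≥
  obs})/(B+1), α = 0.01), and each NUPT is assigned to an episode when
  its posterior reaches 95% (otherwise *unassigned*). For k = 2 the
  lower-identity component is the older episode I.
- **Spatial statistics** — clusters (≥ 2 non-overlapping NUPTs with
  consecutive gaps < 5 kb), cluster collinearity with the donor order
  (Kendall's τ), size–identity rank correlations, windowed density
  tracks (500 kb nuclear / 100 bp plastid), donor-hotspot peaks
  (> mean + 3 sd), and flanking-GC bias (100-bp flanks vs the non-NUPT
  genome background, Mann–Whitney U).
- **Synthetic genomes** — a first-class generator that plants insertions
  with known episode, size law, cluster structure, IR donors, decoy
  low-complexity regions and GC halos, with a full ground-truth table, so
  every stage of the pipeline is scored against known truth.

## Worked example

Run the full pipeline on a simulated dataset (a 10-Mb nuclear genome with
1000 planted insertions from two episodes at 79.05% and 93.1% identity):

```bash
nuptscan run --seed 7 --outdir run7
```

which ends with a summary like (from `run7/report.json`):

```json
{
  "clusters": 174,
  "hits": 1143,
  "ir_redundant": 167,
  "masked_regions": 2,
  "nupts": 1108,
  "nupts_nonredundant": 941
}
```

and a `report.md` reading, in part:

```
## Genome fraction
- plastid DNA fraction: 14.48% raw, 13.33% after IR dedup

## Episodes
- selected k: 2
- component means: 80.53, 93.06
```

Read that as: 1143 local alignments survived the e-value gate, 35 were
removed as low-complexity artifacts or too short, 167 were IR double
counts; the bootstrap test chose two mixture components and the fit
resolved the two planted transfer episodes (true means 79.05 and 93.1),
and 174 clusters of ≥ 2 integrants were chained. Per-NUPT tables (`nupts.*.tsv` + BED6), cluster tables, density
tracks, donor peaks and flanking-GC tests are written alongside.

The same stages are available as separate commands
(`nuptscan simulate | detect | dedup | episodes | spatial | report`) and
as library functions (`nuptscan.align_plastid_to_nuclear`,
`nuptscan.fit_gmm_em`, `nuptscan.detect_clusters`, ...). The mixture
model is a scikit-learn-style estimator:

```python
import numpy as np
from nuptscan import GaussianMixture1D

x = np.concatenate([np.random.normal(79.05, 3.0, 790),
                    np.random.normal(93.10, 2.0, 3840)])
gmm = GaussianMixture1D(n_components=2, random_state=0).fit(x)
gmm.means_    # array([79.0..., 93.1...])
gmm.predict_proba([86.0])
```

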