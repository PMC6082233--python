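# karyomorph

Karyotype morphometry for plant cytotaxonomy: from per-metaphase chromosome
arm measurements to homolog pairing, arm-ratio classification, haploid
karyotype formulas, consensus idiograms and the asymmetry statistics used
to discriminate closely related taxa. The package was built around the
karyotypes of the *Alstroemeria magnifica* complex (2n = 2x = 16, four
varieties) and ships calibrated templates for its ten studied populations,
so every stage can be exercised on realistic synthetic data without any
measurement files.

## What it computes

For a chromosome with short arm *S* and long arm *L* (µm):

- total length CL = S + L (+ satellite),
- arm ratio r = L/S (satellite excluded),
- centromeric asymmetry CA = 100·(L − S)/(L + S),
- morphological class by left-closed arm-ratio bins
  m [1, 1.7), sm [1.7, 3), st [3, 7), t [7, ∞), with a “-sat” suffix for
  satellited chromosomes.

Per metaphase plate (all 2n chromosomes):

- **M<sub>CA</sub>** — intrachromosomal asymmetry: mean of CA over the
  complement,
- **CV<sub>CL</sub>** — interchromosomal asymmetry: 100·sd(CL)/mean(CL)
  (sample sd),
- **TCL** — total length of the diploid complement, Σ CL.

Homologs are paired within a plate by an exact minimum-weight perfect
matching under d(a,b) = |CL<sub>a</sub> − CL<sub>b</sub>|/mean(CL) +
0.5·|r<sub>a</sub> − r<sub>b</sub>|; pairs whose members differ in class or
by more than 15% in length are flagged heteromorphic. Plates of one
population are rank-aligned by decreasing pair length and averaged into a
consensus haploid karyotype, rendered as a formula string (e.g.
`2m + 1sm + 2st + 2st-sat + 1t-sat`) and an idiogram (SVG/JSON).

The synthetic generator inverts this pipeline: given a formula and target
(CV<sub>CL</sub>, M<sub>CA</sub>, TCL), it deterministically calibrates an
idealized complement hitting the targets to well under 1%, then simulates
noisy plates (lognormal length noise, Gaussian arm-fraction noise, optional
homolog heteromorphism) under a single-seed reproducibility contract.

## Worked example

```sh
karyomorph simulate --template 4408 --template 4406 --template 4409 \
    --template 4383 --plates 10 --seed 42 --out plates.csv
karyomorph analyze plates.csv --out out
```

prints

```
4383: 2n = 16, 2m + 2sm + 1st + 2st-sat + 1t-sat
4406: 2n = 16, 2m + 1sm + 2st + 2st-sat + 1t-sat
4408: 2n = 16, 2m + 1sm + 2st + 2st-sat + 1t-sat
4409: 2n = 16, 2m + 1sm + 1st + 2t + 2t-sat
```

— each simulated population keeps the diploid number 16 and recovers its
variety's haploid formula (var. *magnifica* 4408 and var. *sierrae* 4406
share one formula, so four populations yield three distinct strings). The
recomputed population means (CV<sub>CL</sub> %, M<sub>CA</sub> %, TCL µm)
land on the templates' calibration targets:

```
4383  53.5  50.1  111.4
4406  46.4  51.2  187.5
4408  61.7  45.1  127.5
4409  54.5  54.7  174.4
```

`out/` additionally contains per-population summaries (JSON/CSV), consensus
karyotypes with per-pair means and heteromorphism flags, idiogram SVGs, and
the M<sub>CA</sub> vs CV<sub>CL</sub> scatter (TCL as point size) on which
the varieties separate.

The same functionality is available as a library
(`karyomorph.simulate_population`, `karyomorph.consensus_karyotype`,
`karyomorph.summarize_population`, …); see `docs/methods.md` for the model
and its assumptions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

recomputes, from scratch, the headline parameter-recovery quantities: for
populations 4408, 4406, 4409 and 4383 it calibrates the packaged template,
simulates 10 metaphase plates and reports the pipeline's population means
of CV<sub>CL</sub>, M<sub>CA</sub> or TCL as a JSON object keyed t2–t6.
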