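# iccperm

Robust hypothesis testing of two-rater agreement via the intraclass
correlation coefficient ICC(2,1), with a **studentized permutation test**
as the headline method.

## The problem

When two radiologists, instruments or raters score the same `n` subjects,
agreement is commonly summarized by the single-measure, absolute-agreement
intraclass correlation under the two-way random-effects model

```
x_ij = mu + s_i + r_j + e_ij,
ICC(2,1) = sigma_s^2 / (sigma_s^2 + sigma_r^2 + sigma_e^2),
```

estimated from the ANOVA mean squares as

```
rho_hat = (MSB - MSW) / (MSB + (k-1) MSW + (k/n)(MSR - MSW)),   k = 2.
```

The classical tests of `H0: ICC = 0` (the ANOVA F test, Fisher's Z) lean
on bivariate normality, and even the naive permutation test — shuffle one
rater's column, recompute `rho_hat` — requires exchangeability. Real
rating data (skewed, heavy-tailed, variance-coupled) violate both, and
the classical tests then converge to arbitrary rejection levels that no
sample size fixes.

The studentized permutation test divides the estimate by the moment-based
standard deviation surrogate

```
R = rho_hat / tau_n,    tau_n^2 = mu_22 / (mu_20 * mu_02),
mu_pq = (1/n) sum_i (x_i1 - xbar_1)^p (x_i2 - xbar_2)^q,
```

making the permutation distribution asymptotically pivotal. Its empirical
level stays near the nominal 5% across every scenario in the bundled
simulation study — samples as small as n = 10 included — while giving up
at most a couple of percent of power under bivariate normality.

`iccperm` provides: the ANOVA decomposition and ICC(2,1) estimator
(`iccperm.icc`), the four tests (`iccperm.agreement`), seeded generators
for all the study's null and power scenarios (`iccperm.scenarios`), a
Monte-Carlo engine that regenerates the type-I-error and power tables
(`iccperm.simulate`), and a CLI (`iccperm test`, `iccperm simulate`).

## Worked example

`toy.csv` holds five subjects scored by two raters:

```
1,2
2,2
3,4
4,4
5,6
```

```console
$ iccperm test --input toy.csv --seed 1
n = 5 subjects, k = 2 raters   (seed = 1)
ICC(2,1) estimate: 0.8929
method        statistic   p-value  decision (alpha=0.05)
f_test          34.3333    0.0024  reject H0
fisher_z         2.0306    0.0211  reject H0
permute          0.8929    0.0000  reject H0
stu_permute      0.7043    0.0850  fail to reject
```

Reading this: the raters track each other closely (`rho_hat = 0.89`).
The F statistic is MSB/MSW; the Fisher statistic is
`atanh(rho_hat)*sqrt(n-3)`; the naive permutation statistic is `rho_hat`
itself and the studentized one is `rho_hat/tau_n`. Both permutation
p-values are exact fractions of B = 1000 shuffles of the second column
(strict-inequality count, so 0.0000 means no shuffle beat the observed
statistic). At n = 5 the studentized test is — by design — the cautious
one: its resampled null distribution is wide when so few subjects carry
the evidence. `--json` emits the same numbers machine-readably, and
`--method stuperm` (or `f`, `z`, `perm`) selects a single test.

The same four tests run inside a Monte-Carlo study. For example, the
uniform-on-the-unit-circle null (columns dependent but uncorrelated;
2,000 replicates, B = 500):

```console
$ iccperm simulate --mode type1 --scenarios circular --sizes 25 \
    --reps 2000 --B 500 --seed 7 --out demo
```

`demo/type1_wide.csv` then contains (standard-error columns omitted):

```
scenario,param,n,f_test,fisher_z,permute,stu_permute
circular,,25,0.021,0.0135,0.0185,0.0575
```

At a nominal 5% level the F, Fisher and naive permutation tests reject a
true null far too rarely (~1-2%) — they would also miss genuine agreement
— while the studentized test sits at the nominal level. Under
heavy-tailed or variance-coupled scenarios (`t41`, `exp`, `binorm`, ...)
the same command shows the classical tests inflated instead, at 10-20%.

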