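# greybind

Sequence-only prediction of DNA-binding proteins from a 23-component
pseudo amino acid composition (PseAAC) whose last three components are
grey-model coefficients.

The pipeline:

1. **Encoding** — each standard residue is mapped to a number in (0, 1) by
   the logistic transform of its molecular-volume factor score, turning a
   protein into a positive real series.
2. **Grey model** — a GM(2,1) grey dynamic model is fitted to the series
   by least squares: with the cumulative-sum (1-AGO) series `x1` and
   background values `z1(k) = (x1(k)+x1(k-1))/2`, the discrete equations
   `x0(k) - x0(k-1) + a1*x0(k) + a2*z1(k) = b` are solved for the
   minimum-norm least-squares triple `(a1, a2, b)`.
3. **Features** — the 20 amino-acid frequencies plus `|a1|, |a2|, |b|`
   form the 23-D feature vector.
4. **Classifier** — a random forest (560 trees, 5 predictors sampled per
   split by default) classifies sequences as `binding` / `non-binding`,
   evaluated by leave-one-out jackknife or on an independent set with
   per-class and overall success rates.

The `dataset` module additionally provides FASTA I/O, the benchmark
screening filters (minimum length 50, no more than 10 consecutive `X`, a
greedy pairwise-identity ceiling), and a seeded synthetic-sequence
generator with per-class compositional bias so the whole pipeline is
testable without external downloads.

## CLI

```sh
greybind simulate  --n-per-class 50 --seed 7 --out-fasta sim.fasta
greybind extract   --fasta sim.fasta --out features.tsv
greybind filter    --fasta raw.fasta --out clean.fasta --min-length 50 --max-x-run 10
greybind train     --fasta sim.fasta --model-out model.joblib --trees 560 --mtry 5 --seed 1
greybind predict   --model model.joblib --fasta query.fasta --out predictions.tsv
greybind jackknife --fasta sim.fasta --trees 560 --mtry 5 --seed 1 --out report.json
```

Labels are carried either as a trailing `|1` (binding) / `|0`
(non-binding) token on the FASTA header id or in a two-column
`id<TAB>label` sidecar TSV (`--labels`).

## Library use

```python
from greybind import pseaac, generate_synthetic, jackknife, RfConfig

vector = pseaac("MKKRLLAIAG...")          # 23-D feature vector
data = generate_synthetic(50, seed=7)     # labeled two-class dataset
report = jackknife(data, RfConfig(seed=1))
print(report.overall.success_rate)
```
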