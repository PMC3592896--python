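# ipfddi — drug–drug interaction prediction from interaction profile fingerprints

Drug–drug interactions (DDIs) are a leading cause of adverse drug events, and
most of them are discovered only after a drug reaches the market. `ipfddi`
implements a similarity-propagation predictor for pharmacovigilance work: it
takes a database of *known* pairwise interactions and ranks every other drug
pair by how strongly the known network suggests they should interact, carrying
along the pharmacological effect of the interaction that generated each
prediction.

## The model

Each drug *i* is represented by its **interaction profile fingerprint (IPF)**:
the binary vector over the drug universe marking its known interaction
partners, stored as the sparse set of partner positions. Two fingerprints are
compared with the **Tanimoto coefficient** (Jaccard index)

    TC(A, B) = |A ∩ B| / |A ∪ B|.

With M₁ the symmetric binary known-interaction matrix and M₂ the pairwise TC
matrix over fingerprints (zero diagonal), the prediction matrix M₃ scores each
pair by **max-product propagation**:

    S[i][j] = max over known partners k of drug i of M₂[k][j]
    M₃[{i,j}] = max(S[i][j], S[j][i])

i.e. drug *j* is predicted to interact with drug *i* when some known partner
*k* of *i* has a fingerprint similar to *j*'s — and the new pair inherits the
effect text of the known interaction (*i*, *k*) that produced the maximal
score. The intuition: drugs whose interaction profiles overlap tend to be
pharmacologically alike, so an interaction documented for one of them is a
candidate interaction for the other.

Evaluation tools mirror standard practice for link predictors: hold-out
validation (remove a fraction of known edges, rebuild M₂/M₃ from the rest, and
measure how highly the removed edges rank among all non-edges — ROC/AUROC),
and precision / enrichment-factor / one-sided Fisher exact significance
against a user-supplied reference standard of accepted interactions.

## Worked example

The package ships the canonical two-anticholinergic example as a fixture:
oxybutynin and dicyclomine each have eight interaction partners, sharing
seven of the nine drugs in the union of their profiles, so TC = 7/9 ≈ 0.78.
Dicyclomine has a known interaction with haloperidol ("Increased risk of
psychosis and tardive dyskinesia").

```python
from ipfddi import fig1_fixture, write_edges
write_edges(fig1_fixture(), "example.tsv")
```

```
$ ipfddi predict example.tsv -o predictions.tsv
INFO 11 drugs, 16 known interactions, 2 novel predictions at TC>=0.4
$ cat predictions.tsv
drug_a	drug_b	tc	is_known	anchor_drug	similar_drug	effect
d33	dicyclomine	0.78	0	d33	oxybutynin
haloperidol	oxybutynin	0.78	0	haloperidol	dicyclomine	Increased risk of psychosis and tardive dyskinesia
```

Because dicyclomine's profile matches oxybutynin's at TC 0.78, the known
haloperidol–dicyclomine interaction propagates to the novel pair
haloperidol–oxybutynin with that score and effect (and symmetrically, d33 —
a partner unique to oxybutynin — is predicted for dicyclomine).

Hold-out validation on a seeded synthetic class-structured network (the
`simulate` subcommand; same-class drugs share most interaction partners):

```
$ ipfddi simulate -o network.tsv --seed 1
INFO generated 400 drugs, 1443 edges
$ ipfddi holdout network.tsv -o report.json --holdout-fraction 0.15 --seed 1
INFO held out 216 of 1443 edges; AUROC=0.9981 over 47698 negatives
```

An AUROC of 0.998 means the 216 removed known interactions rank almost
entirely above the ~48k never-observed pairs when scored by the model rebuilt
from the remaining 85% of edges — the class structure makes held-out edges
recoverable, which is exactly the signal the method exploits.

Other subcommands: `ipfddi similarity` (export M₂ as long-format TSV),
`ipfddi evaluate` (precision / enrichment factor / Fisher p against a
reference pair list). All commands are deterministic given `--seed` and write
outputs atomically. See `docs/methods.md` for model assumptions, parameter
semantics and numerical conventions.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the worked-example quantity from scratch — it rebuilds the
fingerprints from their partner positions via the library and reports the
rounded Tanimoto coefficient as JSON.
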