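"""Representational similarity of behavioural confusions with word features.

Builds per-participant behavioural confusion RDMs per category and compares
them (Spearman, Fisher z) against phonological (token edit distance) and
semantic (cosine) RDMs, averaging across categories; the paired Wilcoxon
test asks which feature space tracks behaviour better.  Writes
results/rsa_summary.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import RESULTS, SEED, simulate_cohort

from megword import rsa, synthgen


def main() -> None:
    cfg, _, _, cohort = simulate_cohort()
    RESULTS.mkdir(exist_ok=True)
    inventory = synthgen.generate_word_features(cfg, seed=SEED + 17)
    words_per_cat = cfg.n_words // cfg.n_categories

    rows = []
    for i, (trials, behaviour, _) in enumerate(cohort):
        zp, zs = [], []
        for cat in range(cfg.n_categories):
            cat_words = list(range(cat * words_per_cat, (cat + 1) * words_per_cat))
            mask = trials.categories == cat
            try:
                brdm = rsa.behavioural_rdm(
                    trials.words[mask],
                    behaviour["response"].to_numpy()[mask],
                    trials.candidates[mask],
                    labels=cat_words,
                )
                prdm = rsa.phonological_rdm(
                    [inventory.phonemes[w] for w in cat_words], labels=cat_words
                )
                srdm = rsa.semantic_rdm(inventory.vectors[cat_words], labels=cat_words)
                zp.append(rsa.compare_rdms(brdm, prdm)[1])
                zs.append(rsa.compare_rdms(brdm, srdm)[1])
            except ValueError:
                continue
        rows.append(
            {"participant": i, "z_phonological": np.mean(zp), "z_semantic": np.mean(zs)}
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "rsa_summary.tsv", sep="\t", index=False)

    res = rsa.compare_feature_models(
        table["z_phonological"], table["z_semantic"]
    )
    print(f"mean z(phonological) = {table['z_phonological'].mean():.3f}, "
          f"mean z(semantic) = {table['z_semantic'].mean():.3f}")
    print(f"paired Wilcoxon: statistic {res.statistic:.1f}, p {res.pvalue:.3f}")
    print("note: this cohort's errors are driven by representational fidelity, "
          "not word features, so neither model should dominate strongly")
    print(f"wrote {RESULTS / 'rsa_summary.tsv'}")


if __name__ == "__main__":
    main()
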