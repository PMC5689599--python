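"""Compare the three reachability methods on one planted benchmark.

Ranks the disease catalogue by (a) walk+enrichment scoring on
modularized, expanded and whole networks, (b) mean shortest-path
proximity, and (c) direct gene-set overlap, then reports each method's
ROC AUC against the planted gold list.  Higher is better; the overlap
method is expected to do poorly here because the generator plants
*network proximity* (interaction partners), not shared genes.
"""

from obnet import (
    FixtureSpec,
    generate_benchmark,
    oboverlap_rank,
    obsp_disease_ranking,
    roc_auc,
    score_disease_catalogue,
)

spec = FixtureSpec(seed=1)
net, sets, traits, gold, _ = generate_benchmark(spec)
universe = [d for d in traits.traits if d != "obesity"]

rows = []
for mode in ("modularized", "expanded", "whole"):
    _, ranking = score_disease_catalogue(net, sets, traits, "obesity", mode=mode, seed=43)
    rows.append((f"walk+enrichment ({mode})", roc_auc(ranking, gold, universe=universe).auc))
for mode in ("modularized", "expanded"):
    ranking = obsp_disease_ranking(net, sets, traits, "obesity", mode=mode)
    rows.append((f"shortest path ({mode})", roc_auc(ranking, gold, universe=universe).auc))
ranking = oboverlap_rank(traits, "obesity")
rows.append(
    ("gene-set overlap", roc_auc(ranking, gold, score_col="jaccard", ascending=False, universe=universe).auc)
)

print(f"{'method':<32} AUC")
for name, auc in rows:
    print(f"{name:<32} {auc:.3f}")
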