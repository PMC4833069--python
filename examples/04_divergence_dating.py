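"""Date nodes by penalized likelihood with cross-validated rate smoothing.

Branch substitution counts are Poisson in rate x duration.  The Langley-Fitch
model fits one global rate; penalized likelihood (PL) lets every branch have
its own rate but smooths differences between neighboring branches with weight
lambda chosen by leave-one-terminal-branch-out cross-validation.  K-means
groups the fitted branch rates into discrete rate classes.
"""

import numpy as np

from plastidkit import chrono
from plastidkit.io import tree_from_string

rng = np.random.default_rng(4)
newick = "(((A:2,B:2):3,C:5):5,((D:3,E:3):3,F:6):4);"  # true ages in My
tree = tree_from_string(newick)
counts = {}
for nd in tree.postorder_node_iter():
    if nd.parent_node is None:
        continue
    key = frozenset(l.taxon.label for l in nd.leaf_iter())
    counts[key] = int(rng.poisson(60.0 * nd.edge.length))  # ~60 subs/My

constraints = chrono.DatingConstraints(root_age=10.0)
lam, table = chrono.cross_validate_lambda(tree, counts, constraints)
print(f"cross-validated smoothing lambda = {lam:g}")

fit = chrono.fit_pl(tree, counts, constraints, lam)
lf = chrono.fit_langley_fitch(tree, counts, constraints)
print("node ages (My), PL vs LF vs truth:")
truth = {"AB": 2.0, "ABC": 5.0, "DE": 3.0, "DEF": 6.0}
for key, t in truth.items():
    k = frozenset(key)
    print(f"  {key:4s}: PL {fit.ages[k]:5.2f}  LF {lf.ages[k]:5.2f}  true {t:4.1f}")

classes = chrono.classify_rates(fit, k=2, seed=0)
print(f"rate classes (k={classes.k}): means = {[round(m, 2) for m in classes.means]}")
# With clocklike input both methods recover the true ages to within Poisson
# noise; PL's advantage appears when branch rates genuinely vary.
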