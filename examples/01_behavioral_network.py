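"""Build a behavioral network from a small symptom checklist.

Eight patients are scored for ten binary symptoms in two blocks. Parsimony
search groups patients that share symptoms; the consensus network separates
the two blocks, and the tree length counts the symptom gains/losses needed.
"""

from cladelink import (make_toy_fixture, majority_consensus, map_trait_changes,
                       parsimony_score, ratchet_search)

matrix, expected = make_toy_fixture()
print("patients:", ", ".join(matrix.individual_ids))
print("symptoms:", ", ".join(matrix.trait_names))

trees = ratchet_search(matrix, n_iterations=30, seed=0)
consensus = majority_consensus(trees, threshold=0.51)

print(f"\nshortest network length: {trees.score:g} symptom changes "
      f"({len(trees.trees)} equally parsimonious tree(s))")
print("consensus newick:", consensus.to_newick())
print("sanity: independent rescoring gives",
      parsimony_score(trees.trees[0], matrix))

changes = map_trait_changes(trees.trees[0], matrix)
gains = sum(1 for c in changes if c.direction == "gain")
print(f"\nmapped changes: {len(changes)} total ({gains} gains); each change "
      "is one symptom appearing or disappearing along a branch")
print("the A-patients and B-patients form the two sides of the deepest "
      "split, matching the two symptom blocks")
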