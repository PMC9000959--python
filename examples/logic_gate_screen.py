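"""Screen a strain pool for AND-gate circuits and optimize the winner.

Every 2-strain combination from a reduced pool is composed with an auxin
sensor, simulated for 12 h against the full input grids, normalized to the
sensor's dynamic range, and scored min(ON)/max(OFF) against the AND truth
table. Scores above 1 mean every expected-ON output exceeds every
expected-OFF output; those candidates are then refined by optimizing the
strain gains.
"""
from yeastcons import default_library, optimize_gains, screen

library = default_library()
pool = [library[s] for s in
        ["aF_rep_IAA", "bE_rep_IAA", "aF_act_IAA", "bE_act_IAA"]]
sensors = [library["IAA_rep_GFP"]]

result = screen(library, "AND", sizes=(2,), pool=pool, sensors=sensors)
print(f"screened {result.n_topologies} two-strain circuits "
      f"(pool of {len(pool)}, sensor {sensors[0].id}):")
for cand in result.candidates:
    marker = " <- passes the score > 1 bar" if cand.score > 1 else ""
    print(f"  {'+'.join(cand.topology.members):24s} score {cand.score:6.3f}{marker}")

best = result.candidates[0]
print(f"\nbest architecture: {'+'.join(best.topology.members)}")
print("(both inputs repress auxin synthesis; the negative auxin sensor then")
print(" reads HIGH only when both inputs are present — an AND gate)")

optimized = optimize_gains(best, library, seed=0)
print(f"gain optimization: {best.score:.3f} -> {optimized.score:.3f} "
      f"with gains { {k: round(v, 2) for k, v in optimized.gains.items()} }")
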