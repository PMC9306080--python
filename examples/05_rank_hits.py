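"""Hit optimization: beta = f(alpha) + d_i inside an interaction window.

Three classifier-positive candidates with different interaction counts are
ranked inside the 9-12 window.  B has the highest classifier score among
ties but 13 contacts, outside the window, so it is excluded; among the
rest the integer d_i dominates the ranking because f(alpha) < 1.
"""

from ahiot.ps_rank import ThresholdWindow, rank_hits, ranked_hits_frame

predictions = {"A": 0.9, "B": 0.8, "C": 0.7}   # f(alpha), positive-class probability
profiles = {"A": 10, "B": 13, "C": 9}          # d_i, contacts in the docked pose

hits = rank_hits(predictions, profiles, ThresholdWindow(9, 12, target="CXCR4"))
print(ranked_hits_frame(hits).to_string(index=False))
print("rank 1 goes to the best beta inside the window; "
      "B is flagged out (d_i = 13 > 12) despite a good classifier score")
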