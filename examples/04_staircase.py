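"""Estimate an ambiguity threshold with interleaved two-up/two-down staircases.

Two stairs per avatar start at the fully angry (level 1) and fully happy
(level 21) poles of the morph continuum and step toward the category boundary
after every pair of identical categorizations.  The threshold is the mean of
the reversal levels recorded while the one-picture step was in force.
"""

import numpy as np

import rmfaces as rf

# an observer whose subjective ambiguity sits slightly on the angry side
observer = rf.ObserverParams(cat_threshold=10.3, cat_sigma=1.0)
rng = np.random.default_rng(5)

session = rf.run_session(observer, ["f1", "f2", "m1", "m2"], rng)
log = rf.session_log(session)
print(f"total presentations: {len(log)}")
for avatar in ("f1", "f2", "m1", "m2"):
    stairs = [s for s in session if s.avatar_id == avatar]
    thr = rf.ambiguity_threshold(stairs)
    jnd = rf.staircase_jnd(stairs)
    print(f"avatar {avatar}: threshold = {thr:5.2f}, staircase JND = {jnd:4.2f}")
print(f"pooled threshold: {rf.ambiguity_threshold(session):5.2f} "
      f"(true boundary 10.3)")
# A threshold below 11 means a slightly angrier-than-midpoint picture is what
# this observer perceives as emotionally ambiguous.
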