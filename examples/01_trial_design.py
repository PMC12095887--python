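"""Build the stimulus continuum and a randomised trial schedule.

The probe-judgement task crosses 2 emotion conditions x 2 avatar sexes x
2 avatar identities x 7 probe levels x 3 repetitions = 168 analysis trials.
"""

import rmfaces as rf

continuum = rf.build_continuum("f1", "female")
print(f"continuum levels: {continuum.n_levels}")
print(f"anger share at level 11 (ambiguous midpoint): {continuum.anger_share(11)}")
print(f"stimuli across the 4-avatar roster: {len(rf.all_stimulus_ids())}")

anim = rf.build_animation(rf.HAPPY_TO_AMBIGUOUS, continuum)
print(f"happy-to-ambiguous frames: {anim.frames}")
print(f"frame durations (ms): {anim.durations_ms}, mask {anim.mask_duration_ms} ms")

schedule = rf.generate_schedule(seed=1)
analysis = [t for t in schedule if not t.is_training]
print(f"schedule: {len(analysis)} analysis trials + "
      f"{len(schedule) - len(analysis)} training trials")
first = analysis[0]
print(f"first trial: {first.emotion}, avatar {first.avatar_id}, "
      f"probe motion level {first.probe_motion_level} "
      f"(physical level {first.probe_physical_level})")
# Motion level 11 is the animation endpoint; 12-14 lie beyond it in the
# motion direction, which is where a forward (representational-momentum)
# bias shows up as false "equal" responses.
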