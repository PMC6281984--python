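"""Generate a synthetic hybrid EEG-fNIRS session and inspect its structure.

A session follows a 12-trial thumb-tapping block paradigm (60 s pre-rest,
10 s task + 20 s rest per trial, 10 s post-rest) recorded by a 36-channel
fNIRS patch at 9.19 Hz and five EEG electrodes at 256 Hz.  Four channels
over the "motor" region carry a task-evoked oxyhemoglobin rise.
"""

import numpy as np

from hybridphase import synth

spec = synth.SessionSpec(seed=7)
session = synth.generate_session(spec)

print(f"fNIRS samples : {len(session.intensity_690)} at {session.fnirs_rate} Hz")
print(f"EEG samples   : {len(session.eeg)} at {session.eeg_rate} Hz")
print(f"trials        : {session.schedule.n_trials}, onsets at "
      f"{session.schedule.trial_onsets_s[:3]} ... s")
print(f"active chans  : {session.truth['active_channel_ids']}")
print(f"reaction delays (s): {np.round(session.truth['reaction_delays_s'], 2)}")
print(f"rest-period beta bursts: {len(session.truth['beta_bursts_s'])}")

# The printed delays are per-trial reaction times: both the EEG beta rise
# and the hemodynamic response lag the visual cue by these amounts, which
# is what makes fixed cue-anchored windows a weak classification strategy.
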