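"""Event and label vocabularies shared by the simulator and the parser."""

from __future__ import annotations

# behavioral event stream vocabulary
EVENT_TYPES = (
    "fixlight_on",   # fixation-port light illuminated (trial start signal)
    "fix_in",        # snout enters the fixation port
    "fix_out",       # snout exits the fixation port
    "stim_on_left",  # S-left sound onset
    "stim_on_light", # S-right light onset (the new stimulus)
    "catch_mark",    # internal timestamp of the would-be stimulus in catch trials
    "port_in",       # reward-port entry
    "port_out",      # reward-port exit
    "lick",          # sipper-tube lick
    "reward_drop",   # one drop of reward delivered
)

PORTS = ("left", "right", "center", "none")

STIM_EVENTS = {"stim_on_left": "s_left", "stim_on_light": "light", "catch_mark": "catch"}
TRIAL_TYPES = ("s_left", "light", "catch")

# sequence taxonomy for trials and out-of-trial lick bouts
LABELS = (
    "light_lick",
    "left_lick",
    "catch_lick",
    "no_fixation_lick",
    "light_no_lick",
    "catch_no_lick",
    "left_no_lick",
    "early_exit",
    "wrong_port",
)

# the three reward-seeking behaviors toward the new (right) reward port
RIGHT_LICK_LABELS = ("light_lick", "catch_lick", "no_fixation_lick")

# labels that carry a completed lick episode and hence a trial-outcome event
LICK_LABELS = ("light_lick", "left_lick", "catch_lick", "no_fixation_lick", "wrong_port")

EVENT_COLUMNS = ("time_s", "event", "port", "trial_hint")
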