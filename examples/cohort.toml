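# Example configuration: 8 prosthesis-user-mode subjects, 3 trials in each
# of the three sensory conditions (eyes open, eyes closed, weight-bearing
# feedback).  All fields are optional; omitted ones use package defaults.

[cohort]
n_subjects = 8
trials_per_condition = 3
master_seed = 7
conditions = ["EO", "EC", "FB"]

[trial]
duration = 60.0
fs = 100.0
group = "TPU"
mean_load_share = 0.6   # fraction of body weight on the intact limb

[pendulum]
body_mass = 75.0
com_height = 0.95
gravity = 9.81

[controller]
kp = 1.12
kd = 0.35
delay = 0.15
noise_sd = 0.0045
fb_share_gain = 0.5
ec_noise_multiplier = 1.4

[geometry]
stance_width = 0.24
foot_length = 0.25
ankle_to_met5 = 0.15
pin_fraction = 0.66
pin_side = "left"
block_height = 0.0
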