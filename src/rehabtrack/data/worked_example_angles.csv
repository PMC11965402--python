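posture,exercise,trajectory_condition,body_part,predicted_deg,actual_deg,error_deg
sitting_start,ready,none,lower_limb,177.32,180,-2.68
sitting_start,ready,none,lower_limb,135.95,123,4.95
performing_left,hip_flexion,gt160_lt15,right_leg_normal,151.52,148,3.52
performing_right,hip_flexion,gt160_lt15,left_leg_normal,141.35,142,-0.65
performing_left,hip_flexion,gt160_lt15,left_leg_complete,12.49,12.84,-0.34
performing_right,hip_flexion,gt160_lt15,right_leg_complete,3.51,6.1,-2.59
performing_left,hip_external_rotation,gt150_lt30,left_leg_complete,45,46,-1
performing_left,hip_external_rotation,gt150_lt30,right_leg_normal,90,93,-3
performing_left,knee_extension,gt160_lt95,left_leg_complete,85,88,-3
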