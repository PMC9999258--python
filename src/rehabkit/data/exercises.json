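{
  "catalog_version": "1.0",
  "exercises": [
    {"id": "bobath_handshake", "name": "Bobath handshake training", "segment": "upper"},
    {"id": "bobath_flexion_extension", "name": "Bobath flexion and extension", "segment": "upper"},
    {"id": "bobath_external_anterior_flexion_extension", "name": "Bobath external anterior flexion and extension", "segment": "upper"},
    {"id": "bobath_pre_post_rotation", "name": "Bobath pre- and postrotation", "segment": "upper"},
    {"id": "breast_expansion", "name": "Breast expansion exercise", "segment": "upper"},
    {"id": "shoulder_internal_external_rotation", "name": "Shoulder joint internal and external rotation", "segment": "upper"},
    {"id": "shoulder_touch", "name": "Shoulder touch training", "segment": "upper"},
    {"id": "elbow_flexion_touch", "name": "Elbow joint flexion and touch", "segment": "upper"},
    {"id": "flexion_pressure_rotation", "name": "Flexion-pressure rotation forward and backward", "segment": "hand"},
    {"id": "wrist_flexion_extension", "name": "Wrist flexion and extension", "segment": "hand"},
    {"id": "elbow_flexion_wrist_compression", "name": "Elbow flexion and wrist compression training", "segment": "hand"},
    {"id": "finger_to_finger", "name": "Finger-to-finger training", "segment": "hand"},
    {"id": "ball_gripping", "name": "Ball gripping training", "segment": "hand"},
    {"id": "squat", "name": "Squat training", "segment": "lower"},
    {"id": "knee_flexion_extension", "name": "Knee flexion and extension", "segment": "lower"},
    {"id": "knee_internal_external_rotation", "name": "Knee internal and external rotation", "segment": "lower"}
  ]
}
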