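# Generic adult vascular geometry for the 20-vessel upper-extremity domain.
# Columns: vessel_id, length_cm, diameter_mm, h_over_r, youngs_modulus_kpa, is_vein
# Lengths and aortic/branch diameters follow generic arterial-tree tables;
# arm diameters are placeholders overridden by per-patient duplex stations.
vessel_id,length_cm,diameter_mm,h_over_r,youngs_modulus_kpa,is_vein
ascending_aorta,4.0,29.0,0.11,400,0
aortic_arch_a1,2.0,24.0,0.11,400,0
aortic_arch_a2,3.9,22.0,0.11,400,0
thoracic_aorta,15.6,20.0,0.11,400,0
innominate,3.4,12.5,0.13,400,0
left_carotid,20.8,7.4,0.15,700,0
right_carotid,17.7,7.4,0.15,700,0
left_subclavian,3.4,8.5,0.13,400,0
right_subclavian,3.4,8.5,0.13,400,0
vertebral,14.8,3.7,0.20,800,0
axillary_brachial,42.2,5.6,0.15,900,0
radial,23.5,3.0,0.20,900,0
ulnar_proximal,6.7,3.0,0.20,900,0
ulnar_distal,17.1,2.8,0.20,900,0
interosseus,7.9,1.8,0.20,900,0
cephalic_distal,23.5,3.0,0.10,300,1
median_cubital,4.0,4.0,0.10,300,1
cephalic_proximal,25.0,4.0,0.10,300,1
basilic,25.0,4.5,0.10,300,1
axillary_subclavian_vein,10.0,8.0,0.10,300,1
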