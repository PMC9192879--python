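patient,height_right_mm,height_right_pct,height_left_mm,height_left_pct,intercondylar_deg,axis_right_deg,axis_left_deg,volume_mm3,volume_pct,density_right_pre_hu,density_right_post_hu,density_right_pct,density_left_pre_hu,density_left_post_hu,density_left_pct,surface_anterior_right_mm,surface_anterior_left_mm,surface_posterior_right_mm,surface_posterior_left_mm,surface_medial_right_mm,surface_medial_left_mm,surface_lateral_right_mm,surface_lateral_left_mm,surface_superior_right_mm,surface_superior_left_mm
1,1.2,,-3.1,-3.89,0.5,3.3,5.9,-42,-2.3,524.6,406.5,-22.5,498.80,308.60,-36.1,-1.00,-0.51,0.42,-0.67,0.00,-0.30,-0.56,0.00,0.98,-0.80
2,-1.8,-2.58,-0.9,-1.31,-1.7,5.3,-7.0,8,0.5,567.5,376.3,-33.7,455.80,297.20,-34.8,0.25,0.60,-1.00,0.00,0.10,0.20,-0.95,-0.80,-0.95,0.32
3,-1.2,-1.81,-0.4,-0.61,-13.7,-1.6,1.4,54,3.1,571.1,425.1,-25.6,351.10,226.50,-35.5,-0.60,-0.40,0.24,-0.38,0.00,0.50,-1.04,0.80,0.24,-0.44
4,-2.8,-3.75,-1.4,-1.95,-13.5,0.9,3.6,148,9.9,487.7,348.3,-28.6,492.20,303.60,-38.3,-0.80,-0.43,-0.85,-0.24,0.00,-0.50,0.35,0.67,1.00,0.00
5,-1.2,-1.81,2.4,,-7.5,-9.3,-0.3,22,1.2,759.5,511.0,-32.7,580.80,370.60,-36.2,1.00,0.47,1.18,-0.50,1.50,0.00,0.00,0.46,-0.20,0.58
6,-0.8,-1.12,-2.4,-3.38,-13.7,1.2,7.6,20,1.6,663.5,429.6,-35.2,539.60,395.50,-26.7,-0.40,-0.50,-0.50,0.38,0.40,0.00,0.30,-0.39,0.30,0.49
7,-2.3,-3.03,-1.9,-2.48,5.2,6.5,4.8,34,1.7,380.8,236.8,-37.8,372.70,223.80,-38.9,-0.70,1.46,0.40,0.54,0.80,0.00,0.00,0.00,-0.46,-1.00
8,-0.8,-1.21,0.6,,-22.6,11.3,7.7,51,2.7,751.8,466.4,-38.0,651.90,397.20,-39.1,0.48,0.99,0.60,-0.50,-0.55,-0.20,0.00,0.00,0.36,-0.69
9,2.1,,-2.7,-3.18,-17.4,20.5,8.2,69,4.10,556.9,383.6,-31.1,602.20,406.90,-32.4,0.00,0.77,0.00,-0.29,-0.70,0.36,0.70,-0.40,0.75,0.58
10,1.7,,-0.6,-0.72,-11.5,17.2,-5.0,104,5.6,453.4,295.7,-34.8,403.30,269.30,-33.2,0.56,0.65,-0.69,0.80,-0.56,0.65,0.36,-0.51,0.52,0.00
11,-1.4,-1.58,-1.1,-1.27,-11.8,9.7,-1.0,26,2.0,511.1,318.2,-37.7,492.60,336.30,-31.7,-0.33,-0.34,0.60,-0.44,0.69,-0.60,1.00,1.40,-0.40,-0.34
12,-0.8,-1.01,1.1,,-22.0,18.5,-13.3,29,1.7,736.3,506.9,-31.1,698.30,431.00,-38.2,0.63,0.36,-0.02,0.20,0.57,0.50,-0.33,-0.70,0.68,-0.85
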