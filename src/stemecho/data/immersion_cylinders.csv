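# bundled immersion dataset: three cylindrical stem samples, measured
# masses and ultrasonic velocities over soaking time
sample_id,shape,dim1_cm,dim2_cm,dim3_cm,timepoint_h,mass_g,velocity_m_s
cyl6,cylinder,6.00,6.00,,0.0,102.60,4710
cyl6,cylinder,6.00,6.00,,0.1667,106.60,4350
cyl6,cylinder,6.00,6.00,,0.3333,115.80,3860
cyl6,cylinder,6.00,6.00,,0.5,117.20,3480
cyl6,cylinder,6.00,6.00,,0.6667,120.90,3200
cyl6,cylinder,6.00,6.00,,1.0,125.90,3040
cyl6,cylinder,6.00,6.00,,4.0,132.00,2780
cyl6,cylinder,6.00,6.00,,5.0,133.70,2760
cyl6,cylinder,6.00,6.00,,22.0,144.40,2380
cyl6,cylinder,6.00,6.00,,24.0,145.00,2340
cyl6,cylinder,6.00,6.00,,30.0,148.70,2280
cyl6,cylinder,6.00,6.00,,32.0,150.10,1950
cyl6,cylinder,6.00,6.00,,48.0,154.50,1820
cyl6,cylinder,6.00,6.00,,168.0,169.80,1630
cyl6,cylinder,6.00,6.00,,216.0,173.60,1500
cyl7,cylinder,7.00,7.00,,0.0,111.20,4950
cyl7,cylinder,7.00,7.00,,0.1667,122.60,4420
cyl7,cylinder,7.00,7.00,,0.3333,125.70,3950
cyl7,cylinder,7.00,7.00,,0.5,127.30,3690
cyl7,cylinder,7.00,7.00,,0.6667,129.70,3660
cyl7,cylinder,7.00,7.00,,1.0,132.90,3500
cyl7,cylinder,7.00,7.00,,4.0,141.70,2900
cyl7,cylinder,7.00,7.00,,5.0,144.00,2880
cyl7,cylinder,7.00,7.00,,22.0,157.00,2280
cyl7,cylinder,7.00,7.00,,24.0,160.00,2110
cyl7,cylinder,7.00,7.00,,30.0,165.40,2330
cyl7,cylinder,7.00,7.00,,32.0,166.00,2030
cyl7,cylinder,7.00,7.00,,48.0,172.00,1700
cyl7,cylinder,7.00,7.00,,168.0,191.50,1560
cyl7,cylinder,7.00,7.00,,216.0,196.70,1520
cyl10,cylinder,10.00,10.00,,0.0,294.00,5140
cyl10,cylinder,10.00,10.00,,0.1667,311.00,4550
cyl10,cylinder,10.00,10.00,,0.3333,320.80,4430
cyl10,cylinder,10.00,10.00,,0.5,328.70,4340
cyl10,cylinder,10.00,10.00,,0.6667,331.40,4120
cyl10,cylinder,10.00,10.00,,1.0,339.20,3970
cyl10,cylinder,10.00,10.00,,4.0,366.20,3770
cyl10,cylinder,10.00,10.00,,5.0,373.10,3680
cyl10,cylinder,10.00,10.00,,22.0,410.20,2840
cyl10,cylinder,10.00,10.00,,24.0,415.00,2770
cyl10,cylinder,10.00,10.00,,30.0,426.10,2600
cyl10,cylinder,10.00,10.00,,32.0,429.20,2490
cyl10,cylinder,10.00,10.00,,48.0,448.20,2160
cyl10,cylinder,10.00,10.00,,168.0,494.10,1740
cyl10,cylinder,10.00,10.00,,216.0,506.70,1640
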