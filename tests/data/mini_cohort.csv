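participant_id,test_date,age,sex,ergometry,height_cm,weight_kg,vo2max,resting_bla,stage_index,load,bla,rpe
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,1,50.0,1.0,7
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,2,75.0,1.1,8
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,3,100.0,1.5,10
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,4,125.0,2.0,12
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,5,150.0,3.0,14
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,6,175.0,4.0,16
G01,2019-03-01,30.0,male,bicycle,180.0,75.0,40.0,1.0,7,200.0,6.0,18
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,1,5.0,0.9,8
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,2,6.0,1.0,9
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,3,7.0,1.5,10
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,4,8.0,2.0,12
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,5,9.0,3.0,14
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,6,10.0,4.0,15
G02,2019-04-02,40.0,female,treadmill,170.0,65.0,50.0,1.1,7,11.0,6.5,18
G01,2019-09-15,30.0,male,bicycle,180.0,75.0,40.0,1.0,1,50.0,1.0,8
G01,2019-09-15,30.0,male,bicycle,180.0,75.0,40.0,1.0,2,75.0,1.4,10
G01,2019-09-15,30.0,male,bicycle,180.0,75.0,40.0,1.0,3,100.0,2.1,12
G01,2019-09-15,30.0,male,bicycle,180.0,75.0,40.0,1.0,4,125.0,3.2,15
G04,2019-05-05,35.0,male,bicycle,178.0,80.0,38.0,0.9,1,50.0,1.0,8
G04,2019-05-05,35.0,male,bicycle,178.0,80.0,38.0,0.9,2,75.0,,10
G04,2019-05-05,35.0,male,bicycle,178.0,80.0,38.0,0.9,3,100.0,2.2,12
G04,2019-05-05,35.0,male,bicycle,178.0,80.0,38.0,0.9,4,125.0,3.5,14
G05,2019-06-06,28.0,female,bicycle,165.0,60.0,35.0,1.0,1,40.0,1.1,8
G05,2019-06-06,28.0,female,bicycle,165.0,60.0,35.0,1.0,2,60.0,1.6,
G05,2019-06-06,28.0,female,bicycle,165.0,60.0,35.0,1.0,3,80.0,2.8,13
G05,2019-06-06,28.0,female,bicycle,165.0,60.0,35.0,1.0,4,100.0,4.2,16
G06,2019-07-07,45.0,male,treadmill,182.0,85.0,45.0,1.2,1,6.0,1.3,9
G06,2019-07-07,45.0,male,treadmill,182.0,85.0,45.0,1.2,2,8.0,2.4,13
G07,2019-08-08,50.0,female,rowing,168.0,62.0,30.0,1.0,1,40.0,1.0,9
G07,2019-08-08,50.0,female,rowing,168.0,62.0,30.0,1.0,2,60.0,1.8,11
G07,2019-08-08,50.0,female,rowing,168.0,62.0,30.0,1.0,3,80.0,3.1,14
G08,2019-10-10,33.0,male,bicycle,176.0,72.0,42.0,1.0,1,50.0,1.1,8
G08,2019-10-10,33.0,male,bicycle,176.0,72.0,42.0,1.0,2,75.0,30.0,11
G08,2019-10-10,33.0,male,bicycle,176.0,72.0,42.0,1.0,3,100.0,2.9,14
G09,2019-11-11,55.0,female,bicycle,162.0,58.0,25.0,1.0,1,30.0,1.0,9
G09,2019-11-11,55.0,female,bicycle,162.0,58.0,25.0,1.0,2,45.0,1.02,10
G09,2019-11-11,55.0,female,bicycle,162.0,58.0,25.0,1.0,3,60.0,1.05,11
G09,2019-11-11,55.0,female,bicycle,162.0,58.0,25.0,1.0,4,75.0,1.08,12
G09,2019-11-11,55.0,female,bicycle,162.0,58.0,25.0,1.0,5,90.0,1.1,13
G09,2019-11-11,55.0,female,bicycle,162.0,58.0,25.0,1.0,6,105.0,1.15,14
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,1,6.0,1.0,8
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,2,7.0,1.4,9
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,3,8.0,1.3,10
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,4,9.0,2.0,12
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,5,10.0,3.0,14
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,6,11.0,4.1,16
G10,2019-12-12,26.0,male,treadmill,184.0,78.0,52.0,1.0,7,12.0,5.0,17
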