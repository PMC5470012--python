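code,name,category,met_none,met_light,met_medium,met_hard,met_sitting,met_standing
SLE01,sleeping,1,0.95,,,,,
SLE02,lying quietly / reclining,1,1.3,,,,,
PER01,washing and dressing,2,2.0,,,,,
PER02,showering and toweling off,2,2.0,,,,,
FOO01,eating a meal,3,1.5,,,,,
FOO02,cooking and food preparation,3,,,,,1.8,2.5
WAL01,walking,4,,2.8,3.5,4.3,,
WAL02,driving a car,4,2.5,,,,,
WAL03,riding in a bus or train,4,1.3,,,,,
WAL04,bicycling for transportation or sport,4,,4.0,6.8,10.0,,
HOU01,washing dishes,5,1.8,,,,,
HOU02,vacuuming,5,3.3,,,,,
HOU03,doing laundry,5,2.0,,,,,
HOU04,general tidying and cleaning,5,,2.3,3.3,3.8,,
OCC01,office and computer work,6,,,,,1.3,1.8
OCC02,attending a meeting,6,,,,,1.5,1.8
OCC03,light manual work,6,,2.5,3.0,4.0,,
SHO01,grocery shopping,7,2.3,,,,,
SHO02,standing in line / errands,7,1.3,,,,,
LEI01,watching television,8,1.3,,,,,
LEI02,reading,8,,,,,1.3,1.8
LEI03,playing a musical instrument,8,2.3,,,,,
LEI04,handicrafts and hobbies,8,,,,,1.5,1.8
SPO01,running / jogging,9,,6.0,8.3,11.0,,
SPO02,swimming,9,,4.8,6.0,9.8,,
SPO03,Nordic walking,9,,4.8,6.8,9.5,,
SPO04,strength training,9,,3.5,5.0,6.0,,
FAM01,playing with children,10,3.5,,,,,
FAM02,conversation and socializing,10,,,,,1.5,1.8
OUT01,hiking,11,6.0,,,,,
OUT02,fishing,11,3.5,,,,,
GAR01,gardening,12,3.8,,,,,
GAR02,mowing the lawn,12,5.5,,,,,
MIS01,waiting / standing around,13,1.3,,,,,
MIS02,telephone use,13,,,,,1.3,1.5
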