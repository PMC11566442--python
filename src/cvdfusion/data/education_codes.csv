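scheme,code,label,level
v1989,0,No formal education,low
v1989,1,Elementary grade 1,low
v1989,2,Elementary grade 2,low
v1989,3,Elementary grade 3,low
v1989,4,Elementary grade 4,low
v1989,5,Elementary grade 5,low
v1989,6,Elementary grade 6,low
v1989,7,Elementary grade 7,low
v1989,8,Elementary grade 8,low
v1989,9,High school grade 9,low
v1989,10,High school grade 10,low
v1989,11,High school grade 11,low
v1989,12,High school grade 12 (diploma),middle
v1989,13,College 1 year,middle
v1989,14,College 2 years,middle
v1989,15,College 3 years,middle
v1989,16,College 4 years,high
v1989,17,College 5+ years,high
v1989,99,Not stated,unknown
v2003,1,8th grade or less,low
v2003,2,"9th-12th grade, no diploma",low
v2003,3,High school graduate or GED completed,middle
v2003,4,"Some college credit, no degree",middle
v2003,5,Associate degree,middle
v2003,6,Bachelor's degree,high
v2003,7,Master's degree,high
v2003,8,Doctorate or professional degree,high
v2003,9,Unknown,unknown
acs,1,No schooling completed,low
acs,2,Nursery school to grade 4,low
acs,3,Grade 5 or 6,low
acs,4,Grade 7 or 8,low
acs,5,Grade 9,low
acs,6,Grade 10,low
acs,7,Grade 11,low
acs,8,"Grade 12, no diploma",low
acs,9,Grade 12 no diploma (alt coding),low
acs,10,Grade 12 no diploma (alt coding),low
acs,11,Grade 12 no diploma (alt coding),low
acs,12,Grade 12 no diploma (alt coding),low
acs,13,Grade 12 no diploma (alt coding),low
acs,14,Grade 12 no diploma (alt coding),low
acs,15,Grade 12 no diploma (alt coding),low
acs,16,Regular high school diploma,middle
acs,17,GED or alternative credential,middle
acs,18,"Some college, less than 1 year",middle
acs,19,"Some college, 1 or more years, no degree",middle
acs,20,Associate degree,middle
acs,21,Bachelor's degree,high
acs,22,Master's degree,high
acs,23,Professional degree beyond bachelor's,high
acs,24,Doctorate degree,high
acs,0,Not applicable,unknown
nhanes,1,Less than 9th grade,low
nhanes,2,"9th-11th grade (incl. 12th, no diploma)",low
nhanes,3,High school graduate or GED,middle
nhanes,4,Some college or associate degree,middle
nhanes,5,College graduate or above,high
nhanes,7,Refused,unknown
nhanes,9,Don't know,unknown
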